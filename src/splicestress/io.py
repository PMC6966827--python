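"""Readers and writers for the plain-text interchange formats.

TSV tables are written with a fixed column order and float format so that
identical inputs produce byte-identical files. FASTA goes through
Biopython; annotation is GTF-like (tab-separated with gene_id /
transcript_id attributes) and intervals are BED6.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from splicestress.models import GeneModel

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: Dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gtf(genes: Sequence[GeneModel], path: Path) -> None:
    """GTF-like annotation: gene lines plus transcript lines with feature
    lengths stuffed into the attribute field (lengths are the authoritative
    record; the simulator's span geometry is carried by the gene line)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                "\t".join(
                    [g.chrom, "splicestress", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            for iso in g.isoforms:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{iso.isoform_id}"; '
                    f'transcript_length "{iso.transcript_length}"; '
                    f'utr5_length "{iso.utr5_length}"; '
                    f'cds_length "{iso.cds_length}"; '
                    f'utr3_length "{iso.utr3_length}";'
                )
                fh.write(
                    "\t".join(
                        [g.chrom, "splicestress", "transcript", str(g.start + 1),
                         str(g.end), ".", g.strand, ".", attrs]
                    )
                    + "\n"
                )


def write_bed6(df: pd.DataFrame, path: Path, name_col: str = "name") -> None:
    """BED6 from a frame with chrom/start/end and optional name/strand."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[name_col] if name_col in df.columns else ".",
            "score": 0,
            "strand": df["strand"] if "strand" in df.columns else ".",
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed6(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df


def lengths_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for iso in g.isoforms:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "isoform_id": iso.isoform_id,
                    "transcript_length": iso.transcript_length,
                    "utr5_length": iso.utr5_length,
                    "cds_length": iso.cds_length,
                    "utr3_length": iso.utr3_length,
                }
            )
    return pd.DataFrame(rows)


def intron_bed(genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for i, local in enumerate(g.intron_intervals):
            gs, ge = g.genomic_intron(local)
            rows.append(
                {"chrom": g.chrom, "start": gs, "end": ge,
                 "name": f"{g.gene_id}.i{i}", "strand": g.strand}
            )
    return pd.DataFrame(rows)


def read_motifs(path: Path) -> List[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


SCHEMA = {
    "ratios.tsv": "line, condition, gene_id, isoform_id, ratio, reads — per-sample isoform proportions (sum to 1 per gene) with assigned read counts",
    "ratio_truth.tsv": "gene_id, is_responder — genes with the planted infection effect",
    "lengths.tsv": "gene_id, isoform_id, transcript_length, utr5_length, cds_length, utr3_length (bp)",
    "gene_truth.tsv": "gene_id, n_isoforms, utr3_class — constructed 3'UTR mechanism class",
    "events.bed": "BED6 of intron retention events (introns)",
    "events.tsv": "event_id, gene_id, chrom, start, end, strand, flanking exon intervals",
    "retention_counts.tsv": "event_id, line, condition, k_r, k_s, n, covered — retention/splicing supporting read counts",
    "retention_truth.tsv": "event_id, planted, shared, psi_control, psi_infected, effect_lines",
    "variants.tsv": "chrom, pos (0-based), af, is_sqtl, gene_id, distance (bp to gene, 0 inside)",
    "sequences.fa": "gene-body sequences in genomic orientation, one record per gene",
    "elements.bed": "BED6 of predicted hexamer element locations",
    "uorfs.bed": "BED6 of uORF intervals",
    "uorf_truth.tsv": "gene_id, start, end, planted_intron, has_uorf — per intron",
    "annotation.gtf": "GTF-like annotation with gene_id/transcript_id attributes",
    "motifs.txt": "one hexamer per line",
}


def write_schema(path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(SCHEMA, fh, indent=2, sort_keys=True)
        fh.write("\n")
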
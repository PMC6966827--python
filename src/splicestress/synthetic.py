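"""Synthetic data with planted, parameterized effects.

Every generator is deterministic given the config seed, and every planted
effect is recorded in a truth table so downstream stages can be validated
by parameter recovery. Gene coordinates are 0-based half-open; minus-strand
genes keep their features in transcription order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from splicestress.config import ConfigError, SimConfig
from splicestress.models import (
    GeneModel,
    Isoform,
    UTR3_ALT_POLY,
    UTR3_AMBIGUOUS,
    UTR3_SPLICING,
)
from splicestress import sqtl as _sqtl

CONTROL = "control"
INFECTED = "infected"
CONDITIONS = (CONTROL, INFECTED)

GENE_GAP_BP = 25_000
READ_DEPTH_PER_GENE = 100.0

# distinct salts so each generator has an independent, reproducible stream
_SALT_GENES, _SALT_RATIOS, _SALT_EVENTS, _SALT_VARIANTS = 11, 13, 17, 19


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


# ---------------------------------------------------------------------------
# gene models


def gen_gene_models(config: SimConfig) -> List[GeneModel]:
    """Simulate gene/isoform annotations.

    Isoform counts follow ``isoform_count_distribution``; each multi-isoform
    gene is constructed to fall into one of the three 3'UTR mechanism
    classes deterministically (class recorded in ``utr3_class_truth``).
    Within a gene, isoform 0 carries the shortest 5'UTR and the last isoform
    the longest.
    """
    rng = _rng(config, _SALT_GENES)
    dist = np.asarray(config.isoform_count_distribution, dtype=float)
    k_values = rng.choice(np.arange(1, dist.size + 1), size=config.n_genes, p=dist)

    genes: List[GeneModel] = []
    cursor = 1000
    class_cycle = (UTR3_AMBIGUOUS, UTR3_SPLICING, UTR3_ALT_POLY)
    n_multi = 0
    for gi, k in enumerate(k_values):
        gene_id = f"g{gi:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(k)

        # exon/intron geometry of the gene span
        n_introns = int(rng.integers(1, config.max_introns + 1))
        e_lo, e_hi = config.exon_length_range
        i_lo, i_hi = config.intron_length_range
        exon_lens = rng.integers(e_lo, e_hi + 1, size=n_introns + 1)
        intron_lens = rng.integers(i_lo, i_hi + 1, size=n_introns)
        introns: List[Tuple[int, int]] = []
        offset = 0
        for j in range(n_introns):
            offset += int(exon_lens[j])
            introns.append((offset, offset + int(intron_lens[j])))
            offset += int(intron_lens[j])
        span = offset + int(exon_lens[-1])

        # isoform feature lengths (decoupled from the span geometry)
        base5 = int(rng.integers(50, 251))
        step5 = int(rng.integers(50, 201))
        cds = 3 * int(rng.integers(100, 1001))
        base3 = int(rng.integers(100, 501))
        step3 = int(rng.integers(50, 201))

        if k == 1 or config.utr5_only_diversity:
            utr3_class = UTR3_AMBIGUOUS
        else:
            utr3_class = class_cycle[n_multi % 3]
            n_multi += 1

        isoforms: List[Isoform] = []
        for j in range(k):
            utr5 = base5 + j * step5
            if utr3_class == UTR3_AMBIGUOUS:
                utr3_exons = [(0, base3)]
            elif utr3_class == UTR3_ALT_POLY:
                utr3_exons = [(0, base3 + j * step3)]
            else:  # Splicing: vary the exon count of the 3'UTR
                if j % 2 == 0:
                    utr3_exons = [(0, base3)]
                else:
                    a = max(50, base3 // 2)
                    utr3_exons = [(0, a), (a + 100, a + 100 + base3 - a + step3)]
            utr3 = sum(e - s for s, e in utr3_exons)
            isoforms.append(
                Isoform(
                    isoform_id=f"{gene_id}.t{j}",
                    transcript_length=utr5 + cds + utr3,
                    utr5_length=utr5,
                    cds_length=cds,
                    utr3_length=utr3,
                    exon_count=n_introns + 1,
                    utr3_exons=utr3_exons,
                )
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                strand=strand,
                isoforms=isoforms,
                intron_intervals=introns,
                chrom="chrS",
                start=cursor,
                span=span,
                utr3_class_truth=utr3_class,
            )
        )
        cursor += span + GENE_GAP_BP
    return genes


def gene_truth_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "n_isoforms": [g.n_isoforms for g in genes],
            "utr3_class": [g.utr3_class_truth for g in genes],
        }
    )


# ---------------------------------------------------------------------------
# isoform ratios


def _base_mean(rng: np.random.Generator, k: int) -> np.ndarray:
    """Gene-level mean ratio vector, dominant mass on isoform 0 (the
    shortest-5'UTR isoform) so a shift toward the longest-5'UTR isoform
    raises entropy."""
    w = rng.dirichlet(np.full(k, 1.5))
    return np.sort(w)[::-1]


def gen_ratio_samples(
    genes: Sequence[GeneModel], config: SimConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per line × condition × gene Dirichlet isoform ratios with a planted
    infection effect in responder genes.

    Responders get, in the infected condition, their mean shifted by
    ``responder_utr5_shift`` toward the longest-5'UTR isoform (renormalized)
    and their concentration multiplied by ``responder_concentration_factor``.
    Returns ``(ratios, truth)`` where ratios has columns line, condition,
    gene_id, isoform_id, ratio, reads and truth flags responders.
    """
    if not genes:
        raise ConfigError("genes must be non-empty")
    if config.dirichlet_concentration <= 0:
        raise ConfigError("dirichlet_concentration must be > 0")
    rng = _rng(config, _SALT_RATIOS)

    n_resp = int(round(config.responder_fraction * len(genes)))
    multi = [i for i, g in enumerate(genes) if g.n_isoforms >= 2]
    single = [i for i, g in enumerate(genes) if g.n_isoforms < 2]
    order = list(rng.permutation(multi)) + list(rng.permutation(single))
    responder_idx = set(int(i) for i in order[:n_resp])

    lines = [f"line_{i:02d}" for i in range(config.n_lines)]
    conc = config.dirichlet_concentration
    rows_line, rows_cond, rows_gene, rows_iso = [], [], [], []
    rows_ratio, rows_reads = [], []
    for gi, gene in enumerate(genes):
        k = gene.n_isoforms
        m = _base_mean(rng, k)
        is_resp = gi in responder_idx
        if is_resp and k >= 2:
            m_inf = m.copy()
            m_inf[gene.longest_utr5_index()] += config.responder_utr5_shift
            m_inf /= m_inf.sum()
            conc_inf = conc * config.responder_concentration_factor
        else:
            m_inf, conc_inf = m, conc
        for line in lines:
            for cond in CONDITIONS:
                mu, c = (m_inf, conc_inf) if cond == INFECTED else (m, conc)
                p = rng.dirichlet(np.maximum(c * mu, 1e-8)) if k > 1 else np.ones(1)
                p = p / p.sum()
                reads = rng.poisson(READ_DEPTH_PER_GENE * p)
                for j, iso in enumerate(gene.isoforms):
                    rows_line.append(line)
                    rows_cond.append(cond)
                    rows_gene.append(gene.gene_id)
                    rows_iso.append(iso.isoform_id)
                    rows_ratio.append(p[j])
                    rows_reads.append(int(reads[j]))
    ratios = pd.DataFrame(
        {
            "line": rows_line,
            "condition": rows_cond,
            "gene_id": rows_gene,
            "isoform_id": rows_iso,
            "ratio": rows_ratio,
            "reads": rows_reads,
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_responder": [i in responder_idx for i in range(len(genes))],
        }
    )
    return ratios, truth


# ---------------------------------------------------------------------------
# intron retention counts


def gen_retention_counts(
    genes: Sequence[GeneModel], config: SimConfig
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Binomially sampled retention/splicing counts with planted delta-PSI.

    Returns ``(events, counts, truth)``. ``planted_event_fraction`` of
    events get ``PSI_infected = clip(PSI_control + planted_delta_psi)``;
    of those, ``shared_planted_fraction`` carry the effect in every line
    and the rest in a single random line. Coverage per event/sample is
    Poisson(``event_coverage``); ``k_r + k_s = n`` always.
    """
    if not -1.0 < config.planted_delta_psi < 1.0:
        raise ConfigError("planted_delta_psi must lie in (-1, 1)")
    rng = _rng(config, _SALT_EVENTS)

    candidates = [
        (g, local) for g in genes for local in g.intron_intervals
    ]
    if config.n_events > len(candidates):
        raise ConfigError(
            f"n_events={config.n_events} exceeds the {len(candidates)} introns available"
        )
    pick = rng.choice(len(candidates), size=config.n_events, replace=False)

    n_planted = int(round(config.planted_event_fraction * config.n_events))
    n_shared = int(round(config.shared_planted_fraction * n_planted))
    lines = [f"line_{i:02d}" for i in range(config.n_lines)]

    ev_rows, truth_rows, count_rows = [], [], []
    for ei, ci in enumerate(pick):
        gene, local = candidates[int(ci)]
        gs, ge = gene.genomic_intron(local)
        event_id = f"ev{ei:05d}"
        psi_c = float(rng.uniform(0.05, 0.6))
        planted = ei < n_planted
        shared = ei < n_shared
        psi_i = float(np.clip(psi_c + config.planted_delta_psi, 0.0, 1.0)) if planted else psi_c
        if planted and not shared:
            effect_lines = [lines[int(rng.integers(0, len(lines)))]]
        elif planted:
            effect_lines = list(lines)
        else:
            effect_lines = []
        flank = 100
        ev_rows.append(
            {
                "event_id": event_id,
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "start": gs,
                "end": ge,
                "strand": gene.strand,
                "exon_up_start": max(gene.start, gs - flank),
                "exon_up_end": gs,
                "exon_down_start": ge,
                "exon_down_end": min(gene.end, ge + flank),
            }
        )
        truth_rows.append(
            {
                "event_id": event_id,
                "planted": planted,
                "shared": shared,
                "psi_control": psi_c,
                "psi_infected": psi_i,
                "effect_lines": ",".join(effect_lines),
            }
        )
        for line in lines:
            for cond in CONDITIONS:
                psi = psi_i if (cond == INFECTED and line in effect_lines) else psi_c
                n = int(rng.poisson(config.event_coverage))
                k_r = int(rng.binomial(n, psi)) if n > 0 else 0
                count_rows.append(
                    {
                        "event_id": event_id,
                        "line": line,
                        "condition": cond,
                        "k_r": k_r,
                        "k_s": n - k_r,
                        "n": n,
                        "covered": n > 0,
                    }
                )
    return pd.DataFrame(ev_rows), pd.DataFrame(count_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# variants, sequences, elements, uORFs


@dataclass
class VariantBundle:
    variants: pd.DataFrame  # chrom, pos, af, is_sqtl, gene_id, distance
    sequences: Dict[str, str]  # gene_id -> genomic-orientation sequence
    elements: pd.DataFrame  # chrom, start, end, gene_id (hexamer matches)
    uorfs: pd.DataFrame  # chrom, start, end, name, strand
    uorf_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.42) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def gen_variants_and_elements(
    genes: Sequence[GeneModel],
    config: SimConfig,
    retention_events: Optional[pd.DataFrame] = None,
    retention_truth: Optional[pd.DataFrame] = None,
) -> VariantBundle:
    """Variants with a realistic AF spectrum and planted positional bias,
    hexamer-planted gene sequences, and uORF intervals.

    ``sqtl_positional_bias`` of the planted sQTLs go within 100 bp upstream
    (transcription orientation) of a random splice donor of their gene; the
    remainder are placed inside predicted hexamer elements with their
    uniform odds multiplied by ``sqtl_element_enrichment``. When retention
    tables are supplied, uORF placement odds in planted-retention introns
    are multiplied by ``uorf_enrichment``.
    """
    if not genes:
        raise ConfigError("genes must be non-empty")
    if not config.hexamer_set and config.sqtl_element_enrichment != 1.0:
        raise ConfigError("hexamer planting requested with an empty hexamer_set")
    rng = _rng(config, _SALT_VARIANTS)

    # sequences with planted hexamers
    sequences: Dict[str, str] = {}
    elements_rows = []
    element_ivals_local: Dict[str, List[Tuple[int, int]]] = {}
    motifs = list(config.hexamer_set)
    for g in genes:
        arr = _random_sequence(rng, g.span)
        if motifs:
            n_plant = rng.binomial(g.span, config.hexamer_plant_rate)
            if n_plant > 0 and g.span > 6:
                starts = rng.integers(0, g.span - 6, size=n_plant)
                picks = rng.integers(0, len(motifs), size=n_plant)
                for s, m in zip(starts, picks):
                    arr[s : s + 6] = list(motifs[m])
        seq = "".join(arr)
        sequences[g.gene_id] = seq
        ivals = _sqtl.hexamer_scan(seq, motifs) if motifs else []
        element_ivals_local[g.gene_id] = ivals
        for s, e in ivals:
            elements_rows.append(
                {"chrom": g.chrom, "start": g.start + s, "end": g.start + e, "gene_id": g.gene_id}
            )
    elements = pd.DataFrame(elements_rows, columns=["chrom", "start", "end", "gene_id"])

    # variants
    n_sqtl = int(round(config.sqtl_fraction * config.n_variants))
    n_bias = int(round(config.sqtl_positional_bias * n_sqtl))
    gene_idx = rng.integers(0, len(genes), size=config.n_variants)
    afs = config.draw_afs(rng, config.n_variants)
    var_rows = []
    for vi in range(config.n_variants):
        g = genes[int(gene_idx[vi])]
        is_sqtl = vi < n_sqtl
        if is_sqtl and vi < n_bias and g.intron_intervals:
            local = g.intron_intervals[int(rng.integers(0, len(g.intron_intervals)))]
            donor = g.donor_site(local)
            if g.strand == "+":
                pos = int(rng.integers(max(0, donor - _sqtl.DONOR_WINDOW_BP), donor))
            else:
                pos = int(rng.integers(donor, donor + _sqtl.DONOR_WINDOW_BP))
        elif is_sqtl:
            pos = _place_with_element_bias(
                rng, g, element_ivals_local[g.gene_id], config.sqtl_element_enrichment
            )
        else:
            pos = int(rng.integers(g.start - _sqtl.FLANK_BP, g.end + _sqtl.FLANK_BP))
        if g.start <= pos < g.end:
            dist = 0
        else:
            dist = g.start - pos if pos < g.start else pos - g.end + 1
        var_rows.append(
            {
                "chrom": g.chrom,
                "pos": pos,
                "af": float(afs[vi]),
                "is_sqtl": is_sqtl,
                "gene_id": g.gene_id,
                "distance": int(dist),
            }
        )
    variants = pd.DataFrame(var_rows)

    uorfs, uorf_truth = _gen_uorfs(rng, genes, config, retention_events, retention_truth)
    return VariantBundle(variants, sequences, elements, uorfs, uorf_truth)


def _place_with_element_bias(
    rng: np.random.Generator,
    gene: GeneModel,
    local_elements: List[Tuple[int, int]],
    enrichment: float,
) -> int:
    """Place a variant in the gene ± 10 kb window, with the probability of
    landing inside an element equal to element coverage × enrichment."""
    w_start, w_end = gene.start - _sqtl.FLANK_BP, gene.end + _sqtl.FLANK_BP
    window = w_end - w_start
    merged = _sqtl.merge_intervals(local_elements)
    elem_bp = sum(e - s for s, e in merged)
    p_elem = min(1.0, (elem_bp / window) * enrichment)
    if merged and rng.random() < p_elem:
        # uniform over element bases (genomic = gene.start + local)
        offset = int(rng.integers(0, elem_bp))
        for s, e in merged:
            if offset < e - s:
                return gene.start + s + offset
            offset -= e - s
    # uniform over non-element bases of the window
    while True:
        pos = int(rng.integers(w_start, w_end))
        local = pos - gene.start
        if not any(s <= local < e for s, e in merged):
            return pos


def _gen_uorfs(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    config: SimConfig,
    events: Optional[pd.DataFrame],
    truth: Optional[pd.DataFrame],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    planted_introns = set()
    if events is not None and truth is not None and len(events):
        planted_ids = set(truth.loc[truth["planted"], "event_id"])
        for _, ev in events.iterrows():
            if ev["event_id"] in planted_ids:
                planted_introns.add((ev["gene_id"], int(ev["start"]), int(ev["end"])))

    base = config.uorf_base_rate
    odds0 = base / (1.0 - base)
    rows, truth_rows = [], []
    ui = 0
    for g in genes:
        for local in g.intron_intervals:
            gs, ge = g.genomic_intron(local)
            planted = (g.gene_id, gs, ge) in planted_introns
            odds = odds0 * (config.uorf_enrichment if planted else 1.0)
            p = odds / (1.0 + odds)
            has = bool(rng.random() < p)
            truth_rows.append(
                {"gene_id": g.gene_id, "start": gs, "end": ge,
                 "planted_intron": planted, "has_uorf": has}
            )
            if not has:
                continue
            max_len = min(200, ge - gs)
            length = int(rng.integers(20, max_len + 1)) if max_len > 20 else max_len
            u_start = int(rng.integers(gs, ge - length + 1))
            rows.append(
                {
                    "chrom": g.chrom,
                    "start": u_start,
                    "end": u_start + length,
                    "name": f"uorf{ui:05d}",
                    "strand": g.strand,
                }
            )
            ui += 1
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"]),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# full pipeline output


def simulate_to_dir(config: SimConfig, outdir) -> None:
    """Run every generator and write all inputs plus truth tables.

    Identical configs (including the seed) produce byte-identical files.
    """
    from pathlib import Path

    from splicestress import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = gen_gene_models(config)
    ratios, ratio_truth = gen_ratio_samples(genes, config)
    events, counts, ret_truth = gen_retention_counts(genes, config)
    bundle = gen_variants_and_elements(
        genes, config, retention_events=events, retention_truth=ret_truth
    )

    io.write_gtf(genes, outdir / "annotation.gtf")
    io.write_tsv(io.lengths_table(genes), outdir / "lengths.tsv")
    io.write_tsv(gene_truth_table(genes), outdir / "gene_truth.tsv")
    io.write_tsv(ratios, outdir / "ratios.tsv")
    io.write_tsv(ratio_truth, outdir / "ratio_truth.tsv")
    io.write_tsv(events, outdir / "events.tsv")
    io.write_bed6(events.assign(name=events["event_id"]), outdir / "events.bed")
    io.write_tsv(counts, outdir / "retention_counts.tsv")
    io.write_tsv(ret_truth, outdir / "retention_truth.tsv")
    io.write_tsv(bundle.variants, outdir / "variants.tsv")
    io.write_fasta(bundle.sequences, outdir / "sequences.fa")
    if len(bundle.elements):
        io.write_bed6(bundle.elements.assign(name=bundle.elements["gene_id"]),
                      outdir / "elements.bed")
    io.write_bed6(bundle.uorfs, outdir / "uorfs.bed")
    io.write_tsv(bundle.uorf_truth, outdir / "uorf_truth.tsv")
    with open(outdir / "motifs.txt", "w") as fh:
        for m in config.hexamer_set:
            fh.write(m + "\n")
    io.write_schema(outdir / "schema.json")
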
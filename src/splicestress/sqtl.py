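"""Positional analysis of sQTLs against allele-frequency-matched nulls.

Implements strand-aware relative positioning of variants along gene bodies
and introns, AF-matched resampling of null variant sets, exact hexamer
scanning, and element-overlap enrichment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from splicestress.config import InputError

FLANK_BP = 10_000
DONOR_WINDOW_BP = 100


# ---------------------------------------------------------------------------
# relative positions


def relative_positions(
    variants: pd.DataFrame,
    genes: Sequence,
    flank_bp: int = FLANK_BP,
) -> pd.DataFrame:
    """Assign each variant a strand-aware position relative to its gene.

    ``variants`` needs columns ``chrom``, ``pos`` and (optionally)
    ``gene_id``; when ``gene_id`` is absent the nearest gene within
    ``flank_bp`` is used. Returns a copy with columns:

    - ``region``: ``upstream`` / ``body`` / ``downstream`` (transcription
      orientation, so ``upstream`` of a minus-strand gene has higher
      genomic coordinates),
    - ``rel``: in [0, 1] for ``body`` (0 = TSS), distance in bp for flanks,
    - ``metacoord``: single axis with upstream flank at negative bp, body
      on [0, 1], downstream flank at 1 + bp.

    Variants farther than ``flank_bp`` from every gene are dropped; the
    number removed is stored in ``DataFrame.attrs["n_excluded"]``.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    out = variants.copy()
    if "gene_id" not in out.columns:
        out["gene_id"] = _nearest_gene(out, genes, flank_bp)

    regions: List[str] = []
    rels: List[float] = []
    metas: List[float] = []
    keep: List[bool] = []
    for pos, gid in zip(out["pos"].to_numpy(), out["gene_id"]):
        g = gene_by_id.get(gid)
        if g is None:
            keep.append(False)
            regions.append("")
            rels.append(np.nan)
            metas.append(np.nan)
            continue
        region, rel, meta = _gene_relative(int(pos), g, flank_bp)
        if region is None:
            keep.append(False)
            regions.append("")
            rels.append(np.nan)
            metas.append(np.nan)
        else:
            keep.append(True)
            regions.append(region)
            rels.append(rel)
            metas.append(meta)
    out["region"] = regions
    out["rel"] = rels
    out["metacoord"] = metas
    n_excluded = int(len(out) - sum(keep))
    out = out[np.asarray(keep)].reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def _gene_relative(pos: int, gene, flank_bp: int):
    start, end, strand = gene.start, gene.end, gene.strand
    length = end - start
    if start <= pos < end:
        frac = (pos - start) / length
        if strand == "-":
            # flip so 0 is the TSS; position x maps to the base (end-1-x)
            frac = (end - 1 - pos) / length
        return "body", frac, frac
    if pos < start:
        d = start - pos
        side = "upstream" if strand == "+" else "downstream"
    else:
        d = pos - end + 1
        side = "downstream" if strand == "+" else "upstream"
    if d > flank_bp:
        return None, None, None
    meta = -float(d) if side == "upstream" else 1.0 + float(d)
    return side, float(d), meta


def _nearest_gene(variants: pd.DataFrame, genes: Sequence, flank_bp: int) -> List[str]:
    assigned = []
    by_chrom: Dict[str, List] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, pos in zip(variants["chrom"], variants["pos"].to_numpy()):
        best, best_d = None, flank_bp + 1
        for g in by_chrom.get(chrom, ()):
            if g.start <= pos < g.end:
                best, best_d = g, -1
                break
            d = g.start - pos if pos < g.start else pos - g.end + 1
            if d < best_d:
                best, best_d = g, d
        assigned.append(best.gene_id if best is not None else "")
    return assigned


def intron_relative_positions(
    variants: pd.DataFrame,
    genes: Sequence,
    flank_bp: int = 300,
) -> pd.DataFrame:
    """Position variants relative to the nearest intron of their gene.

    0 is the donor (5') end of the intron, 1 the acceptor end; variants in
    the flanking exonic sequence get bp distances outside [0, 1] on the
    ``metacoord`` axis (negative = exonic, 5' of the donor).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for _, v in variants.iterrows():
        g = gene_by_id.get(v["gene_id"])
        if g is None or not g.intron_intervals:
            continue
        pos = int(v["pos"])
        best = None  # (abs distance, metacoord)
        for local in g.intron_intervals:
            gs, ge = g.genomic_intron(local)
            length = ge - gs
            if gs <= pos < ge:
                frac = (pos - gs) / length if g.strand == "+" else (ge - 1 - pos) / length
                best = (0, frac)
                break
            d5 = gs - pos if pos < gs else pos - ge + 1  # genomic-side distance
            if d5 > flank_bp:
                continue
            upstream_of_donor = (pos < gs) == (g.strand == "+")
            meta = -float(d5) if upstream_of_donor else 1.0 + float(d5)
            if best is None or d5 < best[0]:
                best = (d5, meta)
        if best is not None:
            rows.append({**v.to_dict(), "intron_metacoord": best[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene densities


@dataclass
class MetageneDensity:
    """Histogram density over [-flank, 0) ∪ [0, 1] ∪ (1, flank] coordinates."""

    edges: np.ndarray
    widths: np.ndarray
    observed: np.ndarray  # density per bin
    null_densities: np.ndarray  # (n_sets, n_bins)

    @property
    def null_mean(self) -> np.ndarray:
        return self.null_densities.mean(axis=0)

    @property
    def null_sd(self) -> np.ndarray:
        return self.null_densities.std(axis=0, ddof=1)


def metagene_density(
    observed_coords: np.ndarray,
    null_coords: Sequence[np.ndarray],
    n_body_bins: int = 100,
    flank_bp: int = FLANK_BP,
    flank_bin_bp: int = 100,
) -> MetageneDensity:
    """Density of metacoordinates with flank bins in bp and body bins in
    normalized units; every density integrates to 1 over the domain."""
    up = np.arange(-flank_bp, 0, flank_bin_bp, dtype=float)
    body = np.linspace(0.0, 1.0, n_body_bins + 1)
    down = 1.0 + np.arange(flank_bin_bp, flank_bp + flank_bin_bp, flank_bin_bp, dtype=float)
    edges = np.concatenate([up, body, down])
    widths = np.diff(edges)

    def dens(coords: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(coords, bins=edges)
        total = counts.sum()
        if total == 0:
            return np.zeros_like(widths)
        return counts / total / widths

    nulls = np.vstack([dens(np.asarray(c, dtype=float)) for c in null_coords])
    return MetageneDensity(edges=edges, widths=widths,
                           observed=dens(np.asarray(observed_coords, dtype=float)),
                           null_densities=nulls)


def donor_peak_z(density: MetageneDensity) -> float:
    """z-score of the observed density in the bin immediately 5' of the
    feature start (for intron-relative coordinates: just upstream of the
    donor site), relative to the null mean and sd in that bin."""
    idx = int(np.searchsorted(density.edges, 0.0, side="right")) - 2
    sd = density.null_sd[idx]
    if sd == 0:
        return float("nan")
    return float((density.observed[idx] - density.null_mean[idx]) / sd)


# ---------------------------------------------------------------------------
# AF-matched null sampling


def af_matched_sample(
    variants: pd.DataFrame,
    target_mask: np.ndarray,
    n_sets: int = 100,
    af_bin_width: float = 0.02,
    rng: np.random.Generator | None = None,
) -> List[np.ndarray]:
    """Draw ``n_sets`` null variant index sets matching the target AF spectrum.

    Each returned array holds integer positional indices into ``variants``;
    per AF bin (width ``af_bin_width`` on minor allele frequency) the null
    counts equal the target counts exactly. Sampling is without replacement
    within a set; target variants are never candidates.
    """
    rng = rng or np.random.default_rng()
    target_mask = np.asarray(target_mask, dtype=bool)
    af = variants["af"].to_numpy(dtype=float)
    bins = np.floor(af / af_bin_width).astype(int)
    # AF exactly at the upper edge of the top bin folds into it
    bins[af >= 0.5] = int(np.floor(0.5 / af_bin_width - 1e-12))
    target_bins, target_counts = np.unique(bins[target_mask], return_counts=True)

    candidates = {}
    for b, c in zip(target_bins, target_counts):
        pool = np.flatnonzero((bins == b) & ~target_mask)
        if pool.size < c:
            lo, hi = b * af_bin_width, (b + 1) * af_bin_width
            raise InputError(
                f"AF bin [{lo:.3f}, {hi:.3f}) has {pool.size} candidate "
                f"variants but the target needs {c}"
            )
        candidates[b] = pool

    sets = []
    for _ in range(n_sets):
        parts = [rng.choice(candidates[b], size=c, replace=False)
                 for b, c in zip(target_bins, target_counts)]
        sets.append(np.sort(np.concatenate(parts)))
    return sets


# ---------------------------------------------------------------------------
# hexamer scanning and element enrichment


def hexamer_scan(sequence: str, motifs: Sequence[str]) -> List[Tuple[int, int]]:
    """All exact, possibly overlapping matches of the 6-mers in ``motifs``.

    Returns sorted, 0-based half-open intervals. ``N`` never matches.
    """
    motifs = [m for m in motifs]
    for m in motifs:
        if len(m) != 6 or set(m) - set("ACGT"):
            raise InputError(f"motif {m!r} is not a 6-mer over ACGT")
    if not motifs:
        return []
    pattern = re.compile("(?=(" + "|".join(sorted(set(motifs))) + "))")
    return [(m.start(), m.start() + 6) for m in pattern.finditer(sequence)]


def merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def positions_in_intervals(
    positions: np.ndarray, intervals: Sequence[Tuple[int, int]]
) -> np.ndarray:
    """Boolean mask: which positions fall inside any half-open interval."""
    positions = np.asarray(positions)
    if len(intervals) == 0:
        return np.zeros(positions.shape, dtype=bool)
    merged = merge_intervals(intervals)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(positions.shape, dtype=bool)
    mask[ok] = positions[ok] < ends[idx[ok]]
    return mask


@dataclass
class EnrichmentResult:
    observed: float  # fraction of target variants inside an element
    null_mean: float
    null_sd: float
    z: float  # nan when null sd is 0
    p_empirical: float
    null_fractions: np.ndarray


def overlap_enrichment(
    variants: pd.DataFrame,
    target_mask: np.ndarray,
    element_intervals: Dict[str, Sequence[Tuple[int, int]]],
    null_sets: Sequence[np.ndarray],
) -> EnrichmentResult:
    """Fraction of target variants inside any element vs AF-matched nulls.

    A variant counts once no matter how many elements cover it. ``z`` uses
    the null mean and sd; the empirical p carries the add-one correction.
    """
    if len(null_sets) < 20:
        raise InputError("need at least 20 null sets")
    target_mask = np.asarray(target_mask, dtype=bool)

    inside = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    for chrom, ivals in element_intervals.items():
        sel = chroms == chrom
        if sel.any() and len(ivals):
            inside[sel] = positions_in_intervals(pos[sel], ivals)

    observed = float(inside[target_mask].mean())
    null_fracs = np.array([float(inside[idx].mean()) for idx in null_sets])
    mean, sd = float(null_fracs.mean()), float(null_fracs.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (1.0 + int((null_fracs >= observed).sum())) / (1.0 + len(null_fracs))
    return EnrichmentResult(observed, mean, sd, z, p, null_fracs)
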
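"""Characterization of introns: GC, signal normalization, uORF overlap.

Coordinate comparisons are 0-based half-open throughout; inputs using
1-based conventions must be converted by their readers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from splicestress.config import InputError

UORF_MAX_BP = 200


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator.

    Returns NaN (flagged undefined) for all-N or empty sequences.
    """
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise InputError(f"unexpected characters in sequence: {sorted(bad)}")
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def gc_difference(intron_seq: str, flank_seqs: Sequence[str]) -> float:
    """Intron GC minus the mean GC of its flanking exon sequences."""
    flanks = [gc_content(f) for f in flank_seqs]
    return gc_content(intron_seq) - float(np.nanmean(flanks))


def group_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
    log2: bool = False,
) -> Tuple[float, float]:
    """One-tailed Welch t-test of ``group_a`` vs ``group_b``.

    ``alternative='greater'`` tests mean(a) > mean(b). With ``log2`` the
    values are log2-transformed first (as used for intron lengths). Zero
    variance in both groups with equal means yields p = 0.5 by convention.
    Returns (statistic, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs >= 2 values")
    if log2:
        if np.any(a <= 0) or np.any(b <= 0):
            raise InputError("log2 transform requires positive values")
        a, b = np.log2(a), np.log2(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups; p = 0.5 by convention",
                          stacklevel=2)
            return 0.0, 0.5
        # deterministic separation
        sign = 1.0 if a.mean() > b.mean() else -1.0
        p = 0.0 if (sign > 0) == (alternative == "greater") else 1.0
        return sign * np.inf, p
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ChIP signal normalization


def rpkm(counts: np.ndarray, lengths_bp: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """count / ((length/1e3) * (libsize/1e6)); rows = regions, cols = samples."""
    lengths_bp = np.asarray(lengths_bp, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(lengths_bp <= 0):
        raise InputError("region lengths must be > 0")
    if np.any(library_sizes <= 0):
        raise InputError("library sizes must be > 0")
    return np.asarray(counts, dtype=float) / (
        (lengths_bp[:, None] / 1e3) * (library_sizes[None, :] / 1e6)
    )


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Column-wise quantile normalization with ties averaged.

    Every column is mapped onto the mean of the column-sorted values; tied
    entries within a column receive the mean of their tied ranks' target
    quantiles. Idempotent, and all columns share identical sorted values
    afterwards.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InputError("expected a 2-D matrix")
    n, m = X.shape
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        ranks = stats.rankdata(X[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), target)
    return out


@dataclass
class SignalMatrix:
    """Per-region raw counts across samples for exon-intron-exon triplets.

    ``regions`` carries event_id and region in {exon_up, intron, exon_down};
    rows of ``counts`` align with ``regions``.
    """

    counts: np.ndarray  # (n_regions, n_samples)
    lengths_bp: np.ndarray
    library_sizes: np.ndarray
    regions: pd.DataFrame
    samples: Sequence[str]


def normalize_signal(matrix: SignalMatrix, per_region: bool = False) -> pd.DataFrame:
    """RPKM -> quantile normalization -> per-event standardization.

    By default the three regions of each event are pooled per sample and
    standardized to mean 0, sd 1 (sample sd, n-1); ``per_region=True``
    instead standardizes each region across samples.
    """
    vals = quantile_normalize(
        rpkm(matrix.counts, matrix.lengths_bp, matrix.library_sizes)
    )
    df = matrix.regions.copy()
    for j, s in enumerate(matrix.samples):
        df[s] = vals[:, j]
    sample_cols = list(matrix.samples)
    if per_region:
        sub = df[sample_cols].to_numpy()
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        df[sample_cols] = z
        return df
    for _, idx in df.groupby("event_id").groups.items():
        for s in sample_cols:
            v = df.loc[idx, s].to_numpy()
            sd = v.std(ddof=1)
            if sd == 0:
                df.loc[idx, s] = 0.0
            else:
                df.loc[idx, s] = (v - v.mean()) / sd
    return df


# ---------------------------------------------------------------------------
# uORF overlap


def filter_uorfs(uorfs: pd.DataFrame, max_bp: int = UORF_MAX_BP) -> pd.DataFrame:
    """Keep uORFs shorter than ``max_bp`` + 1 (length <= 200 by default)."""
    lengths = uorfs["end"] - uorfs["start"]
    return uorfs[lengths <= max_bp].reset_index(drop=True)


def _interval_overlap(introns: pd.DataFrame, uorfs: pd.DataFrame) -> np.ndarray:
    """Boolean: each intron overlaps >= 1 uORF (half-open intervals)."""
    out = np.zeros(len(introns), dtype=bool)
    by_chrom: Dict[str, np.ndarray] = {}
    for chrom, grp in uorfs.groupby("chrom"):
        ivals = np.array(sorted(zip(grp["start"], grp["end"])))
        by_chrom[chrom] = ivals
    for i, (_, row) in enumerate(introns.iterrows()):
        ivals = by_chrom.get(row["chrom"])
        if ivals is None:
            continue
        s, e = int(row["start"]), int(row["end"])
        j = np.searchsorted(ivals[:, 0], e, side="left")
        out[i] = bool(np.any(ivals[:j, 1] > s))
    return out


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def corrected_logit(x: int, n: int) -> float:
    """logit((x + 0.5) / (n + 1)) — continuity-corrected proportion."""
    return logit((x + 0.5) / (n + 1.0))


def uorf_overlap_test(
    introns: pd.DataFrame,
    uorfs: pd.DataFrame,
    alternative: str = "greater",
) -> Tuple[pd.DataFrame, float, float]:
    """Paired test that positive-delta-PSI introns carry uORFs more often.

    ``introns`` needs chrom/start/end, a ``line`` column, and ``dpsi_sign``
    in {+1, -1}. Per line, the proportions of positive- and negative-sign
    introns overlapping a (length-filtered) uORF are logit-transformed with
    a continuity correction and compared by a paired one-tailed t-test
    across lines. Lines missing either sign are excluded with a warning.
    Returns (per-line table, t statistic, p).
    """
    uorfs = filter_uorfs(uorfs)
    hit = _interval_overlap(introns, uorfs)
    df = introns.copy()
    df["has_uorf"] = hit

    rows = []
    for line, grp in df.groupby("line", sort=True):
        pos = grp[grp["dpsi_sign"] > 0]
        neg = grp[grp["dpsi_sign"] < 0]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(f"line {line}: no introns of one sign, excluded", stacklevel=2)
            continue
        rows.append(
            {
                "line": line,
                "n_pos": len(pos),
                "n_neg": len(neg),
                "prop_pos": pos["has_uorf"].mean(),
                "prop_neg": neg["has_uorf"].mean(),
                "logit_pos": corrected_logit(int(pos["has_uorf"].sum()), len(pos)),
                "logit_neg": corrected_logit(int(neg["has_uorf"].sum()), len(neg)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise InputError("need >= 2 usable lines for the paired t-test")
    res = stats.ttest_rel(table["logit_pos"], table["logit_neg"], alternative=alternative)
    return table, float(res.statistic), float(res.pvalue)
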
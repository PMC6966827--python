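"""Ratio-weighted effective feature lengths and the permutation G-test.

The effective length of a gene feature in a sample is the sum of the
per-isoform feature lengths weighted by that sample's isoform ratios.
Infection-induced changes are classified as increase/decrease/unchanged and
compared to a sample-shuffling null with G-tests (df = 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from splicestress.config import InputError
from splicestress.models import (
    GeneModel,
    UTR3_ALT_POLY,
    UTR3_AMBIGUOUS,
    UTR3_SPLICING,
)

EPS_BP = 1e-6

FEATURES = ("transcript", "utr5", "cds", "utr3")
# effective transcript length with one feature removed
MINUS_FEATURES = ("minus_utr5", "minus_cds", "minus_utr3")

_LENGTH_COLS = {
    "transcript": "transcript_length",
    "utr5": "utr5_length",
    "cds": "cds_length",
    "utr3": "utr3_length",
}


def effective_length(lengths: Sequence[float], ratios: Sequence[float]) -> float:
    """sum(L_i * p_i) for aligned length and ratio vectors."""
    L = np.asarray(lengths, dtype=float)
    p = np.asarray(ratios, dtype=float)
    if L.shape != p.shape:
        raise InputError(f"length/ratio dimension mismatch: {L.shape} vs {p.shape}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InputError(f"ratios sum to {p.sum():.9g}, expected 1")
    return float(L @ p)


def _feature_lengths(lengths: pd.DataFrame, feature: str) -> pd.Series:
    if feature in _LENGTH_COLS:
        return lengths[_LENGTH_COLS[feature]]
    if feature in MINUS_FEATURES:
        removed = _LENGTH_COLS[feature.removeprefix("minus_")]
        return lengths["transcript_length"] - lengths[removed]
    raise InputError(f"unknown feature {feature!r}")


def effective_length_table(
    ratios: pd.DataFrame,
    lengths: pd.DataFrame,
    features: Sequence[str] = FEATURES,
) -> pd.DataFrame:
    """Effective lengths per (line, condition, gene, feature).

    ``ratios`` is tidy with line/condition/gene_id/isoform_id/ratio;
    ``lengths`` is per (gene_id, isoform_id) with the four length columns
    (an optional ``line`` column gives per-line, indel-adjusted lengths).
    """
    on = ["gene_id", "isoform_id"] + (["line"] if "line" in lengths.columns else [])
    merged = ratios.merge(lengths, on=on, validate="many_to_one")
    if len(merged) != len(ratios):
        raise InputError("some isoforms in the ratio table lack length records")
    out_frames = []
    for feat in features:
        L = _feature_lengths(merged, feat)
        tmp = merged.assign(term=merged["ratio"] * L)
        eff = (
            tmp.groupby(["line", "condition", "gene_id"], sort=True)["term"]
            .sum()
            .rename("effective_length")
            .reset_index()
        )
        eff["feature"] = feat
        out_frames.append(eff)
    return pd.concat(out_frames, ignore_index=True)


def delta_table(efflens: pd.DataFrame) -> pd.DataFrame:
    """delta = infected - control per (line, gene, feature)."""
    wide = efflens.pivot_table(
        index=["line", "gene_id", "feature"], columns="condition",
        values="effective_length",
    )
    for cond in ("control", "infected"):
        if cond not in wide.columns:
            raise InputError(f"missing condition {cond!r}")
    out = wide.reset_index()
    out["delta"] = out["infected"] - out["control"]
    return out[["line", "gene_id", "feature", "delta"]]


def classify_deltas(deltas: Sequence[float], eps_bp: float = EPS_BP) -> Tuple[int, int, int]:
    """(increase, decrease, unchanged) counts with tolerance ``eps_bp``."""
    d = np.asarray(deltas, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InputError("deltas must be finite")
    inc = int((d > eps_bp).sum())
    dec = int((d < -eps_bp).sum())
    return inc, dec, int(d.size - inc - dec)


def g_statistic(observed: Sequence[float], expected: Sequence[float]) -> float:
    """G = 2 * sum(O * ln(O/E)); O = 0 terms contribute 0; E = 0 with O > 0
    is floored at 0.5 with a warning."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float).copy()
    bad = (E <= 0) & (O > 0)
    if bad.any():
        warnings.warn("expected count of 0 floored at 0.5", stacklevel=2)
        E[bad] = 0.5
    mask = O > 0
    return float(2.0 * (O[mask] * np.log(O[mask] / E[mask])).sum())


@dataclass
class GTestResult:
    table: pd.DataFrame  # per line x feature: counts, proportions, null props, G, p
    null_proportions: Dict[str, np.ndarray]  # feature -> (n_perm, n_lines, 3)
    bonferroni_alpha: float


def permutation_g_test(
    ratios: pd.DataFrame,
    lengths: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    n_perm: int = 100,
    eps_bp: float = EPS_BP,
    mode: str = "shuffle",
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> GTestResult:
    """Compare observed change-category counts to a permutation null.

    ``mode='shuffle'`` permutes samples across all (line, condition) slots;
    ``mode='swap'`` flips each line's condition pair with probability 1/2.
    Null expected proportions are the mean over permutations per line; G is
    evaluated with df = 2 and a Bonferroni threshold across line x feature
    tests is reported.
    """
    rng = rng or np.random.default_rng()
    efflens = effective_length_table(ratios, lengths, features=features)

    rows = []
    null_store: Dict[str, np.ndarray] = {}
    for feat in features:
        sub = efflens[efflens["feature"] == feat]
        wide = sub.pivot_table(index="gene_id", columns=["line", "condition"],
                               values="effective_length")
        lines = sorted({line for line, _ in wide.columns})
        cols = [(line, cond) for line in lines for cond in ("control", "infected")]
        missing = [c for c in cols if c not in wide.columns]
        if missing:
            raise InputError(f"missing sample columns {missing}")
        E = wide[cols].to_numpy()  # (genes, 2*n_lines), ctrl/inf interleaved
        n_lines = len(lines)
        ctrl_idx = np.arange(0, 2 * n_lines, 2)
        inf_idx = ctrl_idx + 1

        def class_counts(mat: np.ndarray) -> np.ndarray:
            # mat: (genes, n_lines) of deltas -> (n_lines, 3) counts
            inc = (mat > eps_bp).sum(axis=0)
            dec = (mat < -eps_bp).sum(axis=0)
            unch = mat.shape[0] - inc - dec
            return np.stack([inc, dec, unch], axis=1).astype(float)

        obs = class_counts(E[:, inf_idx] - E[:, ctrl_idx])

        null = np.zeros((n_perm, n_lines, 3))
        for pi in range(n_perm):
            if mode == "shuffle":
                perm = rng.permutation(2 * n_lines)
                Ep = E[:, perm]
            elif mode == "swap":
                flips = rng.random(n_lines) < 0.5
                order = np.arange(2 * n_lines).reshape(n_lines, 2)
                order[flips] = order[flips, ::-1]
                Ep = E[:, order.ravel()]
            else:
                raise InputError(f"unknown permutation mode {mode!r}")
            null[pi] = class_counts(Ep[:, inf_idx] - Ep[:, ctrl_idx])
        null_props = null / null.sum(axis=2, keepdims=True)
        null_store[feat] = null_props

        exp_props = null_props.mean(axis=0)  # (n_lines, 3)
        n_genes = E.shape[0]
        for li, line in enumerate(lines):
            G = g_statistic(obs[li], exp_props[li] * n_genes)
            p = float(stats.chi2.sf(G, df=2))
            rows.append(
                {
                    "line": line,
                    "feature": feat,
                    "n_increase": int(obs[li, 0]),
                    "n_decrease": int(obs[li, 1]),
                    "n_unchanged": int(obs[li, 2]),
                    "prop_increase": obs[li, 0] / n_genes,
                    "prop_decrease": obs[li, 1] / n_genes,
                    "prop_unchanged": obs[li, 2] / n_genes,
                    "null_prop_increase": exp_props[li, 0],
                    "null_prop_decrease": exp_props[li, 1],
                    "null_prop_unchanged": exp_props[li, 2],
                    "G": G,
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    return GTestResult(
        table=table,
        null_proportions=null_store,
        bonferroni_alpha=alpha / max(len(table), 1),
    )


# ---------------------------------------------------------------------------
# 3'UTR mechanism classification


def classify_3utr_mechanism(gene: GeneModel) -> str:
    """Classify how a gene's isoforms can change its effective 3'UTR length.

    No 3'UTR length diversity -> NoAnnotatedDiff/Ambiguous; diversity with
    differing 3'UTR exon counts -> Splicing; same exon count with a common
    start and different ends -> Alternate3Poly; anything else -> Ambiguous.
    """
    for iso in gene.isoforms:
        if not iso.utr3_exons:
            raise InputError(f"{iso.isoform_id}: missing 3'UTR records")
    lengths = {iso.utr3_length for iso in gene.isoforms}
    if len(lengths) <= 1 and _structures_identical(gene):
        return UTR3_AMBIGUOUS
    counts = {len(iso.utr3_exons) for iso in gene.isoforms}
    if len(counts) > 1:
        return UTR3_SPLICING
    # same exon count: all exons but the last must be identical, last exons
    # share a start and differ in end
    k = counts.pop()
    for j in range(k - 1):
        if len({iso.utr3_exons[j] for iso in gene.isoforms}) > 1:
            return UTR3_AMBIGUOUS
    last_starts = {iso.utr3_exons[-1][0] for iso in gene.isoforms}
    last_ends = {iso.utr3_exons[-1][1] for iso in gene.isoforms}
    if len(last_starts) == 1 and len(last_ends) > 1:
        return UTR3_ALT_POLY
    return UTR3_AMBIGUOUS


def _structures_identical(gene: GeneModel) -> bool:
    first = gene.isoforms[0].utr3_exons
    return all(iso.utr3_exons == first for iso in gene.isoforms)


def classification_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "utr3_class": [classify_3utr_mechanism(g) for g in genes],
        }
    )
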
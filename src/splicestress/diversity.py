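"""Isoform filtering, Shannon diversity, and the permutation distance test.

The multivariate test treats each sample's isoform-ratio vector for a gene
as a point; the statistic is the between-condition sum of squares relative
to the total (a pseudo-F / R-squared pair) with significance from label
permutations, plus a permutation dispersion-homogeneity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from splicestress.config import InputError

UNCHANGED_EPS = 1e-9


def shannon_entropy(p: Sequence[float]) -> float:
    """H = -sum(p * ln p) in nats, with 0 * ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise InputError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InputError(f"proportions sum to {p.sum():.9g}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def filter_isoforms(
    ratios: pd.DataFrame,
    min_reads: int = 1,
    min_sample_frac: float = 0.9,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop isoforms without more than ``min_reads`` reads in at least
    ``min_sample_frac`` of the samples; renormalize survivors.

    Returns ``(filtered_ratios, gene_status)`` where gene_status flags which
    genes retain >= 2 isoforms and stay in the test set. Genes reduced to a
    single isoform are kept in the table (entropy 0) but not testable.
    """
    if "reads" not in ratios.columns:
        raise InputError("filter_isoforms requires a 'reads' column")
    df = ratios.copy()
    df["sample"] = df["line"].astype(str) + ":" + df["condition"].astype(str)
    n_samples = df["sample"].nunique()

    passing = (
        df.assign(ok=df["reads"] > min_reads)
        .groupby("isoform_id")["ok"]
        .mean()
    )
    keep_iso = set(passing[passing >= min_sample_frac].index)
    out = df[df["isoform_id"].isin(keep_iso)].drop(columns="sample").copy()

    # renormalize within each (line, condition, gene)
    key = ["line", "condition", "gene_id"]
    totals = out.groupby(key)["ratio"].transform("sum")
    out = out[totals > 0].copy()
    totals = out.groupby(key)["ratio"].transform("sum")
    out["ratio"] = out["ratio"] / totals

    n_iso = out.groupby("gene_id")["isoform_id"].nunique()
    status = pd.DataFrame(
        {"gene_id": n_iso.index, "n_isoforms": n_iso.values,
         "testable": n_iso.values >= 2}
    ).reset_index(drop=True)
    out.attrs["n_samples"] = n_samples
    return out, status


# ---------------------------------------------------------------------------
# diversity summaries


def entropy_table(ratios: pd.DataFrame) -> pd.DataFrame:
    """Shannon entropy per (line, condition, gene)."""
    rows = []
    for (line, cond, gene), grp in ratios.groupby(
        ["line", "condition", "gene_id"], sort=True
    ):
        rows.append(
            {"line": line, "condition": cond, "gene_id": gene,
             "entropy": shannon_entropy(grp["ratio"].to_numpy())}
        )
    return pd.DataFrame(rows)


def delta_entropy_table(entropies: pd.DataFrame) -> pd.DataFrame:
    """delta H = H_infected - H_control per (line, gene)."""
    wide = entropies.pivot_table(
        index=["line", "gene_id"], columns="condition", values="entropy"
    )
    for cond in ("control", "infected"):
        if cond not in wide.columns:
            raise InputError(f"missing condition {cond!r}")
    out = wide.reset_index()
    out["delta_entropy"] = out["infected"] - out["control"]
    return out[["line", "gene_id", "delta_entropy"]]


def diversity_shift_summary(
    ratios: pd.DataFrame,
    eps: float = UNCHANGED_EPS,
    gene_info: Optional[pd.DataFrame] = None,
    line_class: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line net diversity shift plus stratified mean entropies.

    Returns ``(per_line, strata)``. per_line has columns line, n_up, n_down,
    net (n_up - n_down) using tolerance ``eps`` on delta H. strata holds the
    mean entropy per (isoform-count stratum, condition[, class]) where
    gene_info supplies gene_id -> n_isoforms and line_class optionally maps
    line -> class label.
    """
    ent = entropy_table(ratios)
    delta = delta_entropy_table(ent)
    per_line = (
        delta.assign(up=delta["delta_entropy"] > eps, down=delta["delta_entropy"] < -eps)
        .groupby("line")[["up", "down"]]
        .sum()
        .rename(columns={"up": "n_up", "down": "n_down"})
        .reset_index()
    )
    per_line["net"] = per_line["n_up"] - per_line["n_down"]

    strata = ent.copy()
    if gene_info is not None:
        strata = strata.merge(gene_info[["gene_id", "n_isoforms"]], on="gene_id")
    else:
        n_iso = ratios.groupby("gene_id")["isoform_id"].nunique().rename("n_isoforms")
        strata = strata.merge(n_iso, on="gene_id")
    group_cols = ["n_isoforms", "condition"]
    if line_class is not None:
        strata = strata.merge(line_class, on="line")
        group_cols.append("class")
    strata = (
        strata.groupby(group_cols)["entropy"].mean().rename("mean_entropy").reset_index()
    )
    return per_line, strata


def stratum_class_model(strata: pd.DataFrame) -> pd.DataFrame:
    """Two-factor least-squares fit of stratum mean entropies on condition
    and class (reported, not part of acceptance)."""
    if "class" not in strata.columns:
        raise InputError("strata must carry a 'class' column")
    import statsmodels.formula.api as smf

    df = strata.rename(columns={"class": "cls"})
    fit = smf.ols("mean_entropy ~ C(condition) + C(cls)", data=df).fit()
    out = pd.DataFrame({"term": fit.params.index, "estimate": fit.params.values,
                        "p_value": fit.pvalues.values})
    return out


# ---------------------------------------------------------------------------
# distance-based multivariate test


@dataclass
class SplicingTestRow:
    p_value: float
    effect_size: float
    homogeneity_p: float
    statistic: float


def _group_ss(X: np.ndarray, mask: np.ndarray) -> Tuple[float, float]:
    """Between-group and total sum of squares for a binary grouping."""
    n = X.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    grand = X.mean(axis=0)
    sst = float(((X - grand) ** 2).sum())
    m1 = X[mask].mean(axis=0)
    m2 = X[~mask].mean(axis=0)
    ssb = float(n1 * ((m1 - grand) ** 2).sum() + n2 * ((m2 - grand) ** 2).sum())
    return ssb, sst


def distance_splicing_test(
    X: np.ndarray,
    labels: Sequence,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> SplicingTestRow:
    """Permutation test for a condition effect on isoform-ratio vectors.

    ``X`` is (samples x isoforms); ``labels`` a two-level condition vector.
    Effect size is the between-condition share of the total squared
    Euclidean distance (R-squared); p carries the (count+1)/(n_perm+1)
    correction. The homogeneity p permutes distances-to-own-centroid
    between groups, testing equality of dispersion.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise InputError(f"need exactly 2 conditions, got {len(levels)}")
    mask = labels == levels[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise InputError("need >= 2 samples per condition")
    if X.shape[1] < 2:
        raise InputError("need >= 2 isoforms")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    rng = rng or np.random.default_rng()

    n = X.shape[0]
    n1 = int(mask.sum())
    ssb_obs, sst = _group_ss(X, mask)
    if sst <= 1e-300:
        return SplicingTestRow(p_value=1.0, effect_size=0.0, homogeneity_p=1.0,
                               statistic=0.0)
    effect = ssb_obs / sst

    # permutation of the binary labels, vectorized via group-1 sums:
    # SSB = (n1*n2/n) * ||m1 - m2||^2 depends only on the group-1 sum
    P = np.zeros((n_perm, n))
    for i in range(n_perm):
        P[i, rng.choice(n, size=n1, replace=False)] = 1.0
    S1 = P @ X  # (n_perm, d)
    total = X.sum(axis=0)
    m1 = S1 / n1
    m2 = (total - S1) / (n - n1)
    ssb_perm = (n1 * (n - n1) / n) * ((m1 - m2) ** 2).sum(axis=1)
    count = int((ssb_perm >= ssb_obs - 1e-12).sum())
    p = (count + 1) / (n_perm + 1)

    # dispersion homogeneity: permute distances-to-own-centroid
    c1 = X[mask].mean(axis=0)
    c2 = X[~mask].mean(axis=0)
    d = np.where(mask, np.linalg.norm(X - c1, axis=1), np.linalg.norm(X - c2, axis=1))
    t_obs = abs(d[mask].mean() - d[~mask].mean())
    Pd = P @ d
    t_perm = np.abs(Pd / n1 - (d.sum() - Pd) / (n - n1))
    hom_count = int((t_perm >= t_obs - 1e-12).sum())
    hom_p = (hom_count + 1) / (n_perm + 1)

    f_stat = (ssb_obs / 1.0) / max(sst - ssb_obs, 1e-300) * (n - 2)
    return SplicingTestRow(p_value=p, effect_size=effect,
                           homogeneity_p=hom_p, statistic=f_stat)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def splicing_test_table(
    ratios: pd.DataFrame,
    n_perm: int = 10_000,
    effect_threshold: float = 0.1,
    homogeneity_alpha: float = 0.05,
    bh_alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    testable_genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run the distance test on every gene of a tidy ratio table.

    A gene is flagged significant when homogeneity p > ``homogeneity_alpha``,
    BH-adjusted p < ``bh_alpha``, and effect size > ``effect_threshold``.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for gene, grp in ratios.groupby("gene_id", sort=True):
        if testable_genes is not None and gene not in set(testable_genes):
            continue
        wide = grp.pivot_table(index=["line", "condition"], columns="isoform_id",
                               values="ratio")
        if wide.shape[1] < 2:
            continue
        labels = wide.index.get_level_values("condition").to_numpy()
        res = distance_splicing_test(wide.to_numpy(), labels, n_perm=n_perm, rng=rng)
        rows.append({"gene_id": gene, "p_value": res.p_value,
                     "effect_size": res.effect_size,
                     "homogeneity_p": res.homogeneity_p})
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_p"] = adjust_bh(out["p_value"])
        out["significant"] = (
            (out["homogeneity_p"] > homogeneity_alpha)
            & (out["bh_p"] < bh_alpha)
            & (out["effect_size"] > effect_threshold)
        )
    return out
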
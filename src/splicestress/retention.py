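"""Bayesian PSI estimation and Bayes-factor delta-PSI comparison.

PSI (percent spliced-in) of an intron is modeled with a Beta posterior on
retention-supporting vs splicing-supporting read counts. Condition
comparisons use the Savage-Dickey density ratio at delta PSI = 0: under
independent uniform priors the prior density of the difference at 0 is
exactly 1, so BF = 1 / posterior_density(0), the posterior density being a
Gaussian-kernel estimate from Monte-Carlo draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from splicestress.config import InputError

BF_THRESHOLD = 10.0
DPSI_THRESHOLD = 0.2


@dataclass
class PsiPosterior:
    alpha: float
    beta: float
    uncovered: bool = False

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def credible_interval(self, level: float = 0.95) -> Tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return (
            float(stats.beta.ppf(lo, self.alpha, self.beta)),
            float(stats.beta.ppf(1.0 - lo, self.alpha, self.beta)),
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


def psi_posterior(
    k_r: float,
    k_s: float,
    prior: Tuple[float, float] = (1.0, 1.0),
    normalizers: Optional[Tuple[float, float]] = None,
) -> PsiPosterior:
    """Beta posterior over PSI from retention (k_r) and splicing (k_s) counts.

    When ``normalizers`` supplies the number of distinct read start
    positions per category, raw counts are converted to effective counts by
    division before updating (junction and body reads have unequal
    opportunity).
    """
    if k_r < 0 or k_s < 0:
        raise InputError("counts must be non-negative")
    a0, b0 = prior
    if a0 <= 0 or b0 <= 0:
        raise InputError("prior parameters must be > 0")
    kr, ks = float(k_r), float(k_s)
    if normalizers is not None:
        nr, ns = normalizers
        if nr <= 0 or ns <= 0:
            raise InputError("normalizers must be > 0")
        kr, ks = kr / nr, ks / ns
    return PsiPosterior(alpha=a0 + kr, beta=b0 + ks, uncovered=(k_r + k_s == 0))


@dataclass
class BayesComparison:
    delta_psi: float  # E[PSI_infected] - E[PSI_control]
    bayes_factor: float
    delta_psi_se: float  # Monte-Carlo SE of the posterior-mean difference
    bayes_factor_se: float
    defined: bool = True

    def significant(self, bf: float = BF_THRESHOLD, dpsi: float = DPSI_THRESHOLD) -> bool:
        return self.defined and self.bayes_factor > bf and abs(self.delta_psi) > dpsi


def delta_psi_bayes_factor(
    ctrl: Tuple[float, float],
    inf: Tuple[float, float],
    n_mc: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    prior: Tuple[float, float] = (1.0, 1.0),
) -> BayesComparison:
    """Savage-Dickey Bayes factor and posterior-mean delta PSI.

    ``ctrl`` and ``inf`` are (k_r, k_s) count pairs. The BF favors a
    nonzero difference; values > 1 are evidence for a change. Uncovered
    events (zero reads in either condition) yield an undefined result.
    """
    if n_mc < 1000:
        warnings.warn("n_mc < 1000 gives unstable density estimates", stacklevel=2)
    rng = rng or np.random.default_rng()
    post_c = psi_posterior(*ctrl, prior=prior)
    post_i = psi_posterior(*inf, prior=prior)
    if post_c.uncovered or post_i.uncovered:
        return BayesComparison(float("nan"), float("nan"), float("nan"),
                               float("nan"), defined=False)

    delta_mean = post_i.mean - post_c.mean
    draws = post_i.sample(n_mc, rng) - post_c.sample(n_mc, rng)
    se = float(draws.std(ddof=1) / np.sqrt(n_mc))

    kde = stats.gaussian_kde(draws)
    dens0 = float(kde(0.0)[0])
    # asymptotic SE of a Gaussian KDE point estimate: sqrt(f R(K) / (n h)),
    # R(K) = 1/(2 sqrt(pi)) for the Gaussian kernel
    h = float(kde.factor * draws.std(ddof=1))
    dens0 = max(dens0, 1e-300)
    dens0_se = np.sqrt(dens0 / (2.0 * np.sqrt(np.pi) * n_mc * h))
    bf = 1.0 / dens0
    bf_se = bf * (dens0_se / dens0)  # delta method on 1/f(0)
    return BayesComparison(delta_psi=float(delta_mean), bayes_factor=float(bf),
                           delta_psi_se=se, bayes_factor_se=float(bf_se))


def compare_counts_table(
    counts: pd.DataFrame,
    n_mc: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    bf_threshold: float = BF_THRESHOLD,
    dpsi_threshold: float = DPSI_THRESHOLD,
) -> pd.DataFrame:
    """Per (event, line) delta-PSI comparison from a tidy count table.

    ``counts`` needs event_id, line, condition, k_r, k_s with conditions
    ``control`` and ``infected``.
    """
    rng = rng or np.random.default_rng()
    rows = []
    wide = counts.pivot_table(
        index=["event_id", "line"], columns="condition", values=["k_r", "k_s"]
    )
    for (event, line), r in wide.iterrows():
        ctrl = (r[("k_r", "control")], r[("k_s", "control")])
        inf = (r[("k_r", "infected")], r[("k_s", "infected")])
        res = delta_psi_bayes_factor(ctrl, inf, n_mc=n_mc, rng=rng)
        rows.append(
            {
                "event_id": event,
                "line": line,
                "delta_psi": res.delta_psi,
                "bayes_factor": res.bayes_factor,
                "defined": res.defined,
                "significant": res.significant(bf_threshold, dpsi_threshold),
                "direction": int(np.sign(res.delta_psi)) if res.defined else 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recurrence across lines


def call_and_recur(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """Cross-line recurrence of significant delta-PSI calls.

    ``results`` is the per (event, line) table from
    :func:`compare_counts_table`. Returns one row per event with the number
    of lines significant-up / significant-down and membership in the
    >= k-line lists by direction.
    """
    n_lines = results["line"].nunique()
    if n_lines < 2:
        raise InputError("need >= 2 lines")
    if k > n_lines:
        raise InputError(f"k={k} exceeds the {n_lines} lines present")
    sig = results[results["significant"]]
    up = sig[sig["direction"] > 0].groupby("event_id").size()
    down = sig[sig["direction"] < 0].groupby("event_id").size()
    events = results["event_id"].drop_duplicates().sort_values()
    out = pd.DataFrame({"event_id": events})
    out["n_up"] = out["event_id"].map(up).fillna(0).astype(int)
    out["n_down"] = out["event_id"].map(down).fillna(0).astype(int)
    out["recurrent_up"] = out["n_up"] >= k
    out["recurrent_down"] = out["n_down"] >= k
    return out.reset_index(drop=True)


def sign_consistency(recurrence: pd.DataFrame, direction: str = "up") -> pd.Series:
    """For events recurrently changed in one direction, the distribution of
    how many other lines called them in the opposite direction."""
    if direction == "up":
        sel = recurrence[recurrence["recurrent_up"]]["n_down"]
    else:
        sel = recurrence[recurrence["recurrent_down"]]["n_up"]
    return sel.value_counts().sort_index()


# ---------------------------------------------------------------------------
# expected multi-set overlap


def expected_multiset_overlap(
    set_sizes: Sequence[int],
    universe_n: int,
    observed_overlap: Optional[int] = None,
    n_sim: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, Optional[float], np.ndarray]:
    """Expected intersection size of independent uniform subsets, plus a
    simulated p-value for an observed overlap.

    Expectation is N * prod(n_i / N). The p-value is the add-one-corrected
    fraction of simulations whose intersection is >= ``observed_overlap``.
    Returns (expectation, p or None, simulated intersection sizes).
    """
    sizes = [int(s) for s in set_sizes]
    if any(s > universe_n for s in sizes):
        raise InputError("set size exceeds universe size")
    if any(s < 0 for s in sizes) or universe_n <= 0:
        raise InputError("sizes and universe must be positive")
    expectation = universe_n * float(np.prod([s / universe_n for s in sizes]))
    rng = rng or np.random.default_rng()
    sims = np.zeros(n_sim, dtype=int)
    for i in range(n_sim):
        member_count = np.zeros(universe_n, dtype=np.int32)
        for s in sizes:
            member_count[rng.choice(universe_n, size=s, replace=False)] += 1
        sims[i] = int((member_count == len(sizes)).sum())
    p = None
    if observed_overlap is not None:
        p = (1.0 + int((sims >= observed_overlap).sum())) / (1.0 + n_sim)
    return expectation, p, sims
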
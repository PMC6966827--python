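"""Simulation configuration and shared error types."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence, Tuple

import numpy as np


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


class InputError(ValueError):
    """Raised when analysis input data violates a precondition."""


_DEFAULT_HEXAMERS = (
    "GAAGAA",
    "TTTCTT",
    "CTCTCT",
    "GGGAAA",
    "TGCATG",
    "ACTAGT",
    "TTCGAA",
    "GTAAGT",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic data generator.

    ``af_spectrum`` is a tuple describing the minor-allele-frequency
    distribution on (0, 0.5]: ``("beta", a, b)`` for a Beta(a, b) scaled to
    (0, 0.5], ``("uniform", lo, hi)``, or ``("point", v)`` for a point mass.
    """

    n_genes: int = 100
    # probability of a gene having 1, 2, ... isoforms
    isoform_count_distribution: Sequence[float] = (0.25, 0.35, 0.25, 0.15)
    n_lines: int = 10
    dirichlet_concentration: float = 50.0
    responder_fraction: float = 0.2
    responder_utr5_shift: float = 0.3
    # concentration multiplier for responder genes in the infected state;
    # < 1 raises the dispersion (and expected entropy) of their ratios
    responder_concentration_factor: float = 0.9
    n_events: int = 200
    event_coverage: float = 30.0
    planted_delta_psi: float = 0.3
    planted_event_fraction: float = 0.2
    # fraction of planted events whose effect is shared by every line;
    # the rest receive the effect in a single random line
    shared_planted_fraction: float = 0.5
    n_variants: int = 5000
    sqtl_fraction: float = 0.05
    af_spectrum: Sequence = ("beta", 0.8, 3.0)
    sqtl_positional_bias: float = 0.5
    hexamer_set: Sequence[str] = _DEFAULT_HEXAMERS
    # expected planted hexamer instances per bp of gene sequence
    hexamer_plant_rate: float = 0.15
    # odds multiplier for a planted-retention intron carrying a uORF
    uorf_enrichment: float = 1.0
    uorf_base_rate: float = 0.15
    # odds multiplier for an (unbiased) sQTL landing inside a predicted
    # hexamer element rather than uniformly in the gene window
    sqtl_element_enrichment: float = 1.0
    # restrict isoform diversity to the 5'UTR (identical CDS/3'UTR per gene)
    utr5_only_diversity: bool = False
    # gene-span geometry: intron count is uniform on [1, max_introns]
    exon_length_range: Tuple[int, int] = (100, 300)
    intron_length_range: Tuple[int, int] = (60, 1000)
    max_introns: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        dist = np.asarray(self.isoform_count_distribution, dtype=float)
        if dist.ndim != 1 or dist.size == 0:
            raise ConfigError("isoform_count_distribution must be a 1-D vector")
        if np.any(dist < 0) or np.any(dist > 1):
            raise ConfigError("isoform_count_distribution entries must lie in [0, 1]")
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"isoform_count_distribution sums to {dist.sum():.12g}, expected 1"
            )
        for name in (
            "responder_fraction",
            "planted_event_fraction",
            "shared_planted_fraction",
            "sqtl_positional_bias",
            "sqtl_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")
        if not -1.0 < self.planted_delta_psi < 1.0:
            raise ConfigError("planted_delta_psi must lie in (-1, 1)")
        if self.event_coverage < 0:
            raise ConfigError("event_coverage must be >= 0")
        if self.uorf_enrichment <= 0 or self.sqtl_element_enrichment <= 0:
            raise ConfigError("odds multipliers must be > 0")
        for name in ("exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ConfigError(f"{name}={lo, hi} must satisfy 0 < lo <= hi")
        if self.max_introns < 1:
            raise ConfigError("max_introns must be >= 1")
        if not 0.0 <= self.hexamer_plant_rate < 1.0:
            raise ConfigError("hexamer_plant_rate must lie in [0, 1)")
        for h in self.hexamer_set:
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ConfigError(f"hexamer {h!r} is not a 6-mer over ACGT")
        spec = tuple(self.af_spectrum)
        if not spec or spec[0] not in ("beta", "uniform", "point"):
            raise ConfigError(f"unknown af_spectrum {self.af_spectrum!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["isoform_count_distribution"] = list(self.isoform_count_distribution)
        d["hexamer_set"] = list(self.hexamer_set)
        d["af_spectrum"] = list(self.af_spectrum)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def draw_afs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` minor allele frequencies from ``af_spectrum``."""
        spec = tuple(self.af_spectrum)
        if spec[0] == "point":
            af = np.full(n, float(spec[1]))
        elif spec[0] == "uniform":
            af = rng.uniform(float(spec[1]), float(spec[2]), size=n)
        else:
            af = 0.5 * rng.beta(float(spec[1]), float(spec[2]), size=n)
        # keep AFs strictly positive and at most 0.5
        return np.clip(af, 1e-4, 0.5)
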
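"""Shared simulation helpers for the test suite."""

import numpy as np
import pandas as pd

from splicestress.config import SimConfig
from splicestress import synthetic as syn


def uorf_sign_table(uorf_enrichment: float, seed: int, n_lines: int = 10,
                    n_genes: int = 80, detect_prob: float = 0.8,
                    null_signs: bool = False):
    """Build a per-line intron table with delta-PSI signs and matching uORFs.

    With ``null_signs=False``, planted-retention introns act as each line's
    positive-sign set and the rest as the negative set (each line detecting
    a random ``detect_prob`` subset), emulating line-specific significance
    calls of a real planted effect. With ``null_signs=True`` every line
    assigns signs independently at random, the calibration null for the
    paired test: sign carries no information about uORF content and
    per-line deviations are independent.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        n_lines=n_lines,
        n_events=n_genes,  # genes always have >= 1 intron
        planted_event_fraction=0.5,
        shared_planted_fraction=1.0,
        uorf_enrichment=uorf_enrichment,
        hexamer_set=(),
        hexamer_plant_rate=0.0,
        n_variants=10,
        seed=seed,
    )
    genes = syn.gen_gene_models(cfg)
    events, _, truth = syn.gen_retention_counts(genes, cfg)
    bundle = syn.gen_variants_and_elements(
        genes, cfg, retention_events=events, retention_truth=truth
    )
    ev = events.merge(truth[["event_id", "planted"]], on="event_id")
    rng = np.random.default_rng(seed + 77)
    rows = []
    for li in range(n_lines):
        detected = ev[rng.random(len(ev)) < detect_prob]
        if null_signs:
            signs = np.where(rng.random(len(detected)) < 0.5, 1, -1)
        else:
            signs = np.where(detected["planted"].to_numpy(), 1, -1)
        for sign, (_, r) in zip(signs, detected.iterrows()):
            rows.append(
                {"chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
                 "line": f"line_{li:02d}", "dpsi_sign": int(sign)}
            )
    return pd.DataFrame(rows), bundle.uorfs
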
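import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicestress.config import ConfigError, SimConfig
from splicestress import diversity as dv
from splicestress import synthetic as syn


class TestGeneModels:
    def test_single_isoform_config(self):
        cfg = SimConfig(n_genes=10, isoform_count_distribution=(1.0,), seed=0)
        genes = syn.gen_gene_models(cfg)
        assert len(genes) == 10
        assert all(g.n_isoforms == 1 for g in genes)

    def test_forced_two_isoforms(self):
        cfg = SimConfig(n_genes=25, isoform_count_distribution=(0.0, 1.0), seed=0)
        genes = syn.gen_gene_models(cfg)
        assert all(g.n_isoforms == 2 for g in genes)

    def test_determinism(self):
        cfg = SimConfig(n_genes=30, seed=42)
        a = syn.gen_gene_models(cfg)
        b = syn.gen_gene_models(SimConfig(n_genes=30, seed=42))
        assert [g.gene_id for g in a] == [g.gene_id for g in b]
        assert all(x.isoforms == y.isoforms for x, y in zip(a, b))
        assert all(x.intron_intervals == y.intron_intervals for x, y in zip(a, b))

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ConfigError, match="sums to"):
            SimConfig(isoform_count_distribution=(0.5, 0.4))

    def test_feature_length_identity(self, small_genes):
        for g in small_genes:
            for iso in g.isoforms:
                assert iso.transcript_length == (
                    iso.utr5_length + iso.cds_length + iso.utr3_length
                )

    def test_introns_disjoint_within_span(self, small_genes):
        for g in small_genes:
            prev = -1
            for s, e in g.intron_intervals:
                assert prev < s < e <= g.span
                prev = e


class TestRatioSamples:
    def test_rows_sum_to_one(self, small_ratios):
        ratios, _ = small_ratios
        sums = ratios.groupby(["line", "condition", "gene_id"])["ratio"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_responder_count_forced(self):
        cfg = SimConfig(n_genes=200, responder_fraction=0.3, seed=5)
        genes = syn.gen_gene_models(cfg)
        _, truth = syn.gen_ratio_samples(genes, cfg)
        assert int(truth["is_responder"].sum()) == 60

    def test_determinism(self, small_cfg, small_genes):
        a, _ = syn.gen_ratio_samples(small_genes, small_cfg)
        b, _ = syn.gen_ratio_samples(small_genes, small_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_concentration(self, small_genes):
        with pytest.raises(ConfigError):
            SimConfig(dirichlet_concentration=0.0)

    def test_null_exchangeability(self):
        # with no planted effect, per-condition mean entropies are
        # identically distributed across replicates
        per_condition = {"control": [], "infected": []}
        for seed in range(50):
            cfg = SimConfig(n_genes=30, n_lines=2, responder_fraction=0.0, seed=seed)
            genes = syn.gen_gene_models(cfg)
            ratios, _ = syn.gen_ratio_samples(genes, cfg)
            ent = dv.entropy_table(ratios)
            for cond, grp in ent.groupby("condition"):
                per_condition[cond].append(grp["entropy"].mean())
        res = stats.mannwhitneyu(per_condition["control"], per_condition["infected"])
        assert res.pvalue > 0.01


class TestRetentionCounts:
    def test_counts_conserved(self, small_retention):
        _, counts, _ = small_retention
        assert (counts["k_r"] + counts["k_s"] == counts["n"]).all()
        assert (counts["k_r"] >= 0).all() and (counts["k_s"] >= 0).all()

    def test_unplanted_delta_unbiased(self):
        cfg = SimConfig(n_genes=80, n_events=100, planted_delta_psi=0.0,
                        planted_event_fraction=0.5, event_coverage=50, seed=3)
        genes = syn.gen_gene_models(cfg)
        _, counts, _ = syn.gen_retention_counts(genes, cfg)
        wide = counts.pivot_table(index=["event_id", "line"], columns="condition",
                                  values=["k_r", "n"])
        psi = wide["k_r"] / wide["n"].replace(0, np.nan)
        dpsi = (psi["infected"] - psi["control"]).dropna()
        se = dpsi.std() / np.sqrt(len(dpsi))
        assert abs(dpsi.mean()) < 3 * se

    def test_zero_coverage_flagged(self):
        cfg = SimConfig(n_genes=30, n_events=20, event_coverage=0.0, seed=1)
        genes = syn.gen_gene_models(cfg)
        _, counts, _ = syn.gen_retention_counts(genes, cfg)
        assert (counts["n"] == 0).all()
        assert (~counts["covered"]).all()

    def test_planted_count_forced(self):
        cfg = SimConfig(n_genes=200, n_events=500, planted_event_fraction=0.1, seed=2)
        genes = syn.gen_gene_models(cfg)
        _, _, truth = syn.gen_retention_counts(genes, cfg)
        assert int(truth["planted"].sum()) == 50

    def test_too_many_events_rejected(self):
        cfg = SimConfig(n_genes=5, n_events=1000, seed=0)
        genes = syn.gen_gene_models(cfg)
        with pytest.raises(ConfigError, match="exceeds"):
            syn.gen_retention_counts(genes, cfg)

    def test_bad_delta_psi(self):
        with pytest.raises(ConfigError):
            SimConfig(planted_delta_psi=1.5)


class TestVariantsAndElements:
    def test_full_positional_bias(self):
        cfg = SimConfig(n_genes=40, n_variants=500, sqtl_fraction=0.2,
                        sqtl_positional_bias=1.0, hexamer_plant_rate=0.0,
                        hexamer_set=(), seed=4)
        genes = syn.gen_gene_models(cfg)
        bundle = syn.gen_variants_and_elements(genes, cfg)
        by_id = {g.gene_id: g for g in genes}
        sqtls = bundle.variants[bundle.variants["is_sqtl"]]
        assert len(sqtls) == 100
        for _, v in sqtls.iterrows():
            g = by_id[v["gene_id"]]
            ok = False
            for local in g.intron_intervals:
                donor = g.donor_site(local)
                if g.strand == "+":
                    ok |= donor - 100 <= v["pos"] < donor
                else:
                    ok |= donor <= v["pos"] < donor + 100
            assert ok, f"sQTL at {v['pos']} not upstream of any donor"

    def test_point_mass_af(self):
        cfg = SimConfig(n_genes=20, n_variants=200, af_spectrum=("point", 0.5),
                        hexamer_set=(), hexamer_plant_rate=0.0, seed=0)
        genes = syn.gen_gene_models(cfg)
        bundle = syn.gen_variants_and_elements(genes, cfg)
        assert (bundle.variants["af"] == 0.5).all()

    def test_uorf_null_odds(self):
        # uorf_enrichment=1 -> overlap odds equal between planted and
        # non-planted introns (pooled over replicates)
        tables = []
        for seed in range(20):
            cfg = SimConfig(n_genes=60, n_events=60, planted_event_fraction=0.5,
                            uorf_enrichment=1.0, hexamer_set=(),
                            hexamer_plant_rate=0.0, n_variants=10, seed=seed)
            genes = syn.gen_gene_models(cfg)
            events, _, truth = syn.gen_retention_counts(genes, cfg)
            bundle = syn.gen_variants_and_elements(
                genes, cfg, retention_events=events, retention_truth=truth)
            tables.append(bundle.uorf_truth)
        pooled = pd.concat(tables)
        ct = pd.crosstab(pooled["planted_intron"], pooled["has_uorf"])
        _, p = stats.fisher_exact(ct.to_numpy())
        assert p > 0.01

    def test_uorf_lengths_bounded(self):
        cfg = SimConfig(n_genes=50, uorf_base_rate=0.5, hexamer_set=(),
                        hexamer_plant_rate=0.0, n_variants=10, seed=9)
        genes = syn.gen_gene_models(cfg)
        bundle = syn.gen_variants_and_elements(genes, cfg)
        lengths = bundle.uorfs["end"] - bundle.uorfs["start"]
        assert (lengths <= 200).all() and (lengths > 0).all()

    def test_variants_within_window(self):
        cfg = SimConfig(n_genes=30, n_variants=1000, hexamer_set=(),
                        hexamer_plant_rate=0.0, seed=2)
        genes = syn.gen_gene_models(cfg)
        bundle = syn.gen_variants_and_elements(genes, cfg)
        assert (bundle.variants["distance"] <= 10_000).all()


class TestFileDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_genes=15, n_lines=3, n_events=10, n_variants=200, seed=8)
        syn.simulate_to_dir(cfg, tmp_path / "a")
        syn.simulate_to_dir(cfg, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert "ratios.tsv" in files_a and "schema.json" in files_a
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name
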
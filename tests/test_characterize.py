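import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from splicestress.config import InputError
from splicestress import characterize as chz


class TestGcContent:
    def test_all_gc(self):
        assert chz.gc_content("GCGC") == 1.0

    def test_no_gc(self):
        assert chz.gc_content("ATAT") == 0.0

    def test_half(self):
        assert chz.gc_content("ATGC") == 0.5

    def test_all_n_undefined(self):
        assert np.isnan(chz.gc_content("NNNN"))

    def test_n_excluded_from_denominator(self):
        assert chz.gc_content("GCNN") == 1.0

    def test_bad_character_rejected(self):
        with pytest.raises(InputError):
            chz.gc_content("ACGU")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=500))
    @settings(max_examples=100, deadline=None)
    def test_brute_force_oracle(self, seq):
        acgt = [c for c in seq if c in "ACGT"]
        if not acgt:
            assert np.isnan(chz.gc_content(seq))
        else:
            expected = sum(c in "GC" for c in acgt) / len(acgt)
            assert chz.gc_content(seq) == pytest.approx(expected, abs=1e-12)

    def test_gc_difference(self):
        assert chz.gc_difference("GCGC", ["ATAT", "ATGC"]) == pytest.approx(0.75)


class TestGroupCompare:
    def test_identical_groups_half(self):
        with pytest.warns(UserWarning, match="zero variance"):
            stat, p = chz.group_compare([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 0.5

    def test_large_shift(self, rng):
        b = rng.normal(0, 1, size=100)
        a = b + 10
        stat, p = chz.group_compare(a, b, alternative="greater")
        # closed-form check against scipy's two-sided Welch test
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert p == pytest.approx(ref.pvalue / 2, rel=1e-9)
        assert p < 1e-10

    def test_log2_transform(self, rng):
        a = np.exp2(rng.normal(10, 1, size=50))
        b = np.exp2(rng.normal(9, 1, size=50))
        _, p = chz.group_compare(a, b, alternative="greater", log2=True)
        assert p < 0.01
        with pytest.raises(InputError):
            chz.group_compare([-1.0, 2.0], [1.0, 2.0], log2=True)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            chz.group_compare([1.0], [1.0, 2.0])


class TestSignalNormalization:
    def test_rpkm_unit_case(self):
        out = chz.rpkm(np.array([[10.0]]), np.array([1000.0]), np.array([1e6]))
        assert out[0, 0] == pytest.approx(10.0, abs=1e-9)

    def test_rpkm_zero_length_rejected(self):
        with pytest.raises(InputError):
            chz.rpkm(np.ones((1, 1)), np.array([0.0]), np.array([1e6]))

    def test_quantile_2x2_hand_case(self):
        X = np.array([[1.0, 3.0], [2.0, 4.0]])
        out = chz.quantile_normalize(X)
        assert np.allclose(out, [[2.0, 2.0], [3.0, 3.0]])

    def test_quantile_idempotent_and_columns_identical(self, rng):
        X = rng.normal(size=(40, 6))
        q = chz.quantile_normalize(X)
        sorted_cols = np.sort(q, axis=0)
        for j in range(1, 6):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0])
        assert np.allclose(chz.quantile_normalize(q), q, atol=1e-12)

    def test_quantile_ties_averaged(self):
        X = np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0]])
        out = chz.quantile_normalize(X)
        # tied entries in column 0 share the mean of the two lowest targets
        assert out[0, 0] == out[1, 0]

    def test_triplet_standardization(self):
        m = chz.SignalMatrix(
            counts=np.array([[1.0], [2.0], [3.0]]),
            lengths_bp=np.array([1000.0, 1000.0, 1000.0]),
            library_sizes=np.array([1e6]),
            regions=pd.DataFrame({"event_id": ["e1"] * 3,
                                  "region": ["exon_up", "intron", "exon_down"]}),
            samples=["s1"],
        )
        out = chz.normalize_signal(m)
        assert np.allclose(out["s1"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_per_event_mean_zero_sd_one(self, rng):
        n_events = 10
        regions = pd.DataFrame({
            "event_id": np.repeat([f"e{i}" for i in range(n_events)], 3),
            "region": ["exon_up", "intron", "exon_down"] * n_events,
        })
        m = chz.SignalMatrix(
            counts=rng.poisson(50, size=(3 * n_events, 4)).astype(float) + 1,
            lengths_bp=rng.integers(200, 2000, size=3 * n_events).astype(float),
            library_sizes=np.full(4, 2e6),
            regions=regions,
            samples=[f"s{j}" for j in range(4)],
        )
        out = chz.normalize_signal(m)
        for _, grp in out.groupby("event_id"):
            for s in ("s0", "s1", "s2", "s3"):
                assert grp[s].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp[s].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestUorfOverlap:
    def test_proportion_and_logit(self):
        assert chz.logit(0.5) == 0.0
        assert chz.corrected_logit(4, 10) == pytest.approx(chz.logit(4.5 / 11))

    def test_length_filter(self):
        uorfs = pd.DataFrame({"chrom": ["c"] * 3, "start": [0, 0, 0],
                              "end": [100, 200, 300]})
        kept = chz.filter_uorfs(uorfs)
        assert kept["end"].tolist() == [100, 200]

    def test_overlap_proportion(self):
        introns = pd.DataFrame({
            "chrom": "c", "start": np.arange(0, 1000, 100),
            "end": np.arange(50, 1050, 100),
            "line": "l0", "dpsi_sign": 1,
        })
        uorfs = pd.DataFrame({"chrom": ["c"] * 4,
                              "start": [10, 110, 210, 310],
                              "end": [40, 140, 240, 340]})
        hit = chz._interval_overlap(introns, uorfs)
        assert hit.sum() == 4 and hit.mean() == pytest.approx(0.4)

    def test_paired_test_detects_planted_difference(self, rng):
        rows = []
        for li in range(8):
            for i in range(60):
                rows.append({"chrom": "c", "start": 100 * i, "end": 100 * i + 50,
                             "line": f"l{li}", "dpsi_sign": 1,
                             "hit": rng.random() < 0.5})
            for i in range(60, 120):
                rows.append({"chrom": "c", "start": 100 * i, "end": 100 * i + 50,
                             "line": f"l{li}", "dpsi_sign": -1,
                             "hit": rng.random() < 0.1})
        introns = pd.DataFrame(rows)
        # build uORFs exactly under the flagged introns
        hits = introns[introns["hit"]].drop_duplicates(subset=["start"])
        uorfs = pd.DataFrame({"chrom": "c", "start": hits["start"] + 5,
                              "end": hits["start"] + 45})
        table, t, p = chz.uorf_overlap_test(introns, uorfs)
        assert p < 0.05 and t > 0

    def test_line_without_negatives_excluded(self):
        introns = pd.DataFrame({
            "chrom": "c", "start": [0, 100, 0, 100, 0, 100],
            "end": [50, 150, 50, 150, 50, 150],
            "line": ["l0", "l0", "l1", "l1", "l2", "l2"],
            "dpsi_sign": [1, -1, 1, -1, 1, 1],
        })
        uorfs = pd.DataFrame({"chrom": ["c"], "start": [10], "end": [40]})
        with pytest.warns(UserWarning, match="excluded"):
            table, _, _ = chz.uorf_overlap_test(introns, uorfs)
        assert set(table["line"]) == {"l0", "l1"}
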
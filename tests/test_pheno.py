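"""Scaled stripe positions, rank-sum shift tests, nuclei geometry, profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoreseq import pheno
from evoreseq.containers import EmbryoRecord, ProfileTrace
from evoreseq.recurrence import ad_fisher

from oracles import fisher_oracle, ranksum_oracle


def embryo(length, stripes=(), nuclei=(), **kw):
    return EmbryoRecord(
        embryo_id=kw.get("embryo_id", "e1"),
        population=kw.get("population", "p1"),
        generation=kw.get("generation", 4),
        length_um=length,
        stripes_um=np.asarray(stripes, dtype=float),
        nuclei_um=np.asarray(nuclei, dtype=float).reshape(-1, 2),
    )


class TestScalePositions:
    def test_simple_ratio(self):
        scaled = pheno.scale_positions(embryo(500.0, [140.0]))
        assert scaled[0] == pytest.approx(28.0)

    def test_anterior_origin_is_zero(self):
        scaled = pheno.scale_positions(embryo(500.0, [0.0, 250.0]))
        assert scaled[0] == 0.0

    def test_round_trip_recovers_coordinates(self, rng):
        length = 560.0
        coords = np.sort(rng.uniform(0, length, size=7))
        scaled = pheno.scale_positions(embryo(length, coords))
        assert np.allclose(scaled / 100.0 * length, coords)


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        assert pheno.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_small_sample_exact_enumeration(self):
        # {1,2} vs {3,4}: 6 assignments, the observed split is one of two
        # extremes -> two-sided p = 1/3
        assert pheno.rank_sum_test([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 4), (2, 5), (4, 4)])
    def test_matches_permutation_oracle(self, n, m, rng):
        for _ in range(5):
            pooled = rng.choice(1000, size=n + m, replace=False).astype(float)
            x, y = pooled[:n], pooled[n:]
            assert pheno.rank_sum_test(x, y) == pytest.approx(
                ranksum_oracle(x, y), rel=1e-9
            )

    def test_large_samples_use_tie_corrected_normal(self, rng):
        x = rng.normal(0, 1, size=300)
        y = rng.normal(0.5, 1, size=300)
        p = pheno.rank_sum_test(x, y)
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert p == pytest.approx(float(ref))


class TestStripeShift:
    def test_identical_groups_not_significant(self, rng):
        a = rng.normal(37, 1.5, size=(20, 7))
        table = pheno.stripe_shift_test(a, a.copy())
        assert (table["p"] == 1.0).all()
        assert not table["significant"].any()

    def test_clear_shift_detected_with_fdr(self, rng):
        a = rng.normal(37.2, 1.2, size=(60, 7))
        b = rng.normal(36.1, 1.2, size=(217, 7))
        table = pheno.stripe_shift_test(a, b)
        assert (table["q"] <= table["p"] * 7).all()
        assert table["significant"].all()
        assert table["shift_pct_el"].mean() == pytest.approx(-1.1, abs=0.3)

    def test_rejects_degenerate_groups(self):
        with pytest.raises(ValueError):
            pheno.stripe_shift_test(np.ones((1, 7)), np.ones((5, 7)))


class TestLengthSummary:
    def test_single_record_median_is_its_length(self):
        medians, _ = pheno.length_summary([embryo(551.0)])
        assert medians["median_um"].iloc[0] == 551.0

    def test_odd_sized_toy_median(self):
        records = [embryo(x) for x in (540.0, 550.0, 570.0)]
        medians, _ = pheno.length_summary(records)
        assert medians["median_um"].iloc[0] == 550.0

    def test_pairwise_generation_tests(self):
        records = [embryo(500.0 + i, generation=4) for i in range(10)] + [
            embryo(540.0 + i, generation=8) for i in range(10)
        ]
        medians, tests = pheno.length_summary(records)
        assert len(medians) == 2
        assert len(tests) == 1
        assert tests["p"].iloc[0] < 0.01


class TestInternucleiDistances:
    def test_three_four_five_triangle(self):
        d, mean = pheno.internuclei_distances(
            embryo(500.0, nuclei=[(0, 0), (3, 4)])
        )
        assert d.tolist() == [5.0]
        assert mean == 5.0

    def test_uniform_spacing(self):
        nuclei = [(6.5 * i, 0.0) for i in range(10)]
        d, mean = pheno.internuclei_distances(embryo(500.0, nuclei=nuclei))
        assert np.allclose(d, 6.5)
        assert mean == pytest.approx(6.5)

    def test_matches_brute_force_on_random_nuclei(self, rng):
        nuclei = np.column_stack(
            [np.sort(rng.uniform(0, 500, 10)), rng.uniform(-5, 5, 10)]
        )
        d, mean, trace = pheno.internuclei_distances(
            embryo(500.0, nuclei=nuclei), trace=True
        )
        brute = [
            np.sqrt(
                (nuclei[i, 0] - nuclei[i + 1, 0]) ** 2
                + (nuclei[i, 1] - nuclei[i + 1, 1]) ** 2
            )
            for i in range(9)
        ]
        assert np.allclose(d, brute)
        assert mean == pytest.approx(np.mean(brute))
        assert np.allclose(trace["x_um"], nuclei[1:, 0])

    def test_requires_two_nuclei(self):
        with pytest.raises(ValueError):
            pheno.internuclei_distances(embryo(500.0, nuclei=[(1.0, 1.0)]))


class TestAggregateCounts:
    def test_two_experimenters_averaged(self):
        counts = pd.DataFrame(
            {
                "embryo_id": ["e1", "e1"],
                "experimenter": ["A", "B"],
                "count": [12, 14],
            }
        )
        out = pheno.aggregate_counts(counts)
        assert out["mean_count"].iloc[0] == 13.0

    def test_single_experimenter_unchanged(self):
        counts = pd.DataFrame(
            {"embryo_id": ["e1"], "experimenter": ["A"], "count": [12]}
        )
        assert pheno.aggregate_counts(counts)["mean_count"].iloc[0] == 12.0

    def test_fixture_of_six_embryos_matches_hand_computation(self):
        counts = pd.DataFrame(
            {
                "embryo_id": [f"e{i}" for i in range(6)] * 2,
                "group": ["g4"] * 3 + ["g8"] * 3 + ["g4"] * 3 + ["g8"] * 3,
                "experimenter": ["A"] * 6 + ["B"] * 6,
                "count": [10, 12, 14, 16, 18, 20, 12, 14, 16, 18, 20, 22],
            }
        )
        per_embryo = pheno.aggregate_counts(counts)
        assert per_embryo["mean_count"].tolist() == [11, 13, 15, 17, 19, 21]
        summary = pheno.summarize_counts(per_embryo, ["group"])
        g4 = summary.loc[summary["group"] == "g4"].iloc[0]
        assert g4["mean"] == pytest.approx(13.0)
        assert g4["se"] == pytest.approx(np.std([11, 13, 15], ddof=1) / np.sqrt(3))


class TestProfiles:
    def test_peak_normalization(self):
        trace = ProfileTrace(
            positions_um=np.array([0.0, 100.0, 200.0]),
            intensity=np.array([1.0, 4.0, 2.0]),
            posterior_um=500.0,
        )
        out = pheno.normalize_posterior_profile(trace)
        assert out.intensity.max() == 1.0
        assert np.allclose(out.intensity, [0.25, 1.0, 0.5])

    def test_constant_trace_becomes_all_ones(self):
        trace = ProfileTrace(
            positions_um=np.array([0.0, 10.0]),
            intensity=np.array([3.0, 3.0]),
            posterior_um=20.0,
        )
        assert np.all(pheno.normalize_posterior_profile(trace).intensity == 1.0)

    def test_posterior_alignment_and_interpolation(self):
        # two embryos of different lengths, both ending at their posterior:
        # after alignment both end at 0 and interpolate onto a shared grid
        t1 = ProfileTrace(
            positions_um=np.array([400.0, 450.0, 500.0]),
            intensity=np.array([1.0, 2.0, 4.0]),
            posterior_um=500.0,
        )
        t2 = ProfileTrace(
            positions_um=np.array([460.0, 510.0, 560.0]),
            intensity=np.array([2.0, 3.0, 6.0]),
            posterior_um=560.0,
        )
        a1 = pheno.normalize_posterior_profile(t1)
        a2 = pheno.normalize_posterior_profile(t2)
        assert a1.positions_um[-1] == 0.0 and a2.positions_um[-1] == 0.0
        grid = pheno.align_profiles([t1, t2])
        assert grid["position_from_posterior_um"].iloc[-1] == pytest.approx(0.0)
        # manual linear interpolation on the 3-point toy trace at -75 um
        expected = 0.25 + (0.5 - 0.25) * (25 / 50)
        row = grid.loc[grid["position_from_posterior_um"] == -75.0]
        assert row["trace0"].iloc[0] == pytest.approx(expected)

    def test_zero_peak_rejected(self):
        trace = ProfileTrace(
            positions_um=np.array([0.0, 1.0]),
            intensity=np.array([0.0, 0.0]),
            posterior_um=10.0,
        )
        with pytest.raises(ValueError):
            pheno.normalize_posterior_profile(trace)


class TestViability:
    def test_single_replicate_forced_arithmetic(self):
        records = pd.DataFrame(
            {"group": ["anc"], "replicate": [1], "n_embryos": [200],
             "n_eclosed": [137]}
        )
        out = pheno.viability_summary(records)
        assert out["mean_pct"].iloc[0] == pytest.approx(68.5)
        assert np.isnan(out["se_pct"].iloc[0])

    def test_zero_survivors(self):
        records = pd.DataFrame(
            {"group": ["g"], "replicate": [1], "n_embryos": [100],
             "n_eclosed": [0]}
        )
        assert pheno.viability_summary(records)["mean_pct"].iloc[0] == 0.0

    def test_three_replicates_mean_and_se(self):
        records = pd.DataFrame(
            {
                "group": ["g"] * 3,
                "replicate": [1, 2, 3],
                "n_embryos": [100, 100, 100],
                "n_eclosed": [70, 74, 78],
            }
        )
        out = pheno.viability_summary(records)
        assert out["mean_pct"].iloc[0] == pytest.approx(74.0)
        expected_se = 100 * np.std([0.70, 0.74, 0.78], ddof=1) / np.sqrt(3)
        assert out["se_pct"].iloc[0] == pytest.approx(expected_se)

    def test_rejects_more_eclosed_than_plated(self):
        records = pd.DataFrame(
            {"group": ["g"], "replicate": [1], "n_embryos": [10],
             "n_eclosed": [11]}
        )
        with pytest.raises(ValueError):
            pheno.viability_summary(records)


class TestProportionTest:
    def test_equal_proportions_give_p_one(self):
        assert pheno.proportion_test(5, 50, 5, 50) == 1.0

    def test_yolk_fraction_contrast_is_highly_significant(self):
        # 6% vs 1% at n = 1000 nuclei per sample
        assert pheno.proportion_test(60, 1000, 10, 1000) < 0.001

    def test_extreme_table_matches_enumeration(self):
        p = pheno.proportion_test(0, 10, 10, 10)
        assert p == pytest.approx(fisher_oracle(0, 10, 10, 0), rel=1e-9)

    def test_agrees_exactly_with_allele_depth_fisher(self, rng):
        for _ in range(20):
            k1, k2 = rng.integers(0, 15, size=2)
            n1, n2 = k1 + rng.integers(1, 15), k2 + rng.integers(1, 15)
            p1 = pheno.proportion_test(k1, n1, k2, n2)
            res = ad_fisher(k1, n1 - k1, k2, n2 - k2, min_alt=0, min_depth=0)
            assert p1 == res.p

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            pheno.proportion_test(5, 4, 1, 10)
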
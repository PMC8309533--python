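"""RH binning and the nonparametric testing engine.

The Mann-Whitney implementation is checked against an independent
full-enumeration oracle: for tie-free samples the exact two-sided p-value
is recomputed by enumerating every assignment of the pooled observations
to the two groups.
"""

import itertools
import math

import numpy as np
import pytest

from breathmss import (
    RHBinning,
    assign_rh_subgroup,
    bonferroni,
    kruskal_wallis,
    mann_whitney_u,
    subgroup_analysis,
)


def exact_mwu_p(x, y):
    """Brute-force two-sided Mann-Whitney p by full enumeration.

    Enumerates all C(m+n, m) splits of the pooled sample, computes the U
    statistic of the first group for each, and doubles the smaller tail
    probability of the observed U (capped at 1).
    """
    x, y = list(x), list(y)
    pooled = x + y
    m = len(x)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yj in ys if xi > yj)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    n_total = len(us)
    p_low = np.sum(us <= u_obs) / n_total
    p_high = np.sum(us >= u_obs) / n_total
    return min(1.0, 2.0 * min(p_low, p_high))


class TestRHBinning:
    @pytest.mark.parametrize(
        "rh,label",
        [
            (25.0, "20-30"),
            (30.0, "30-40"),  # boundary: left-closed convention
            (39.99, "30-40"),
            (40.0, "40-50"),
            (50.0, "40-50"),  # last edge belongs to the top bin
            (20.0, "20-30"),
        ],
    )
    def test_bin_assignment(self, rh, label):
        assert assign_rh_subgroup(rh) == label

    def test_out_of_range_is_unbinned(self):
        assert assign_rh_subgroup(19.9) is None
        assert assign_rh_subgroup(50.1) is None

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            RHBinning(edges=(20.0, 20.0, 40.0))

    def test_fixture_bin_counts(self, study_metadata):
        breath = study_metadata[study_metadata["sample_type"] == "breath"]
        counts = breath["rh_purge"].map(assign_rh_subgroup).value_counts()
        assert counts.to_dict() == {"20-30": 24, "30-40": 25, "40-50": 34}
        ref = study_metadata[study_metadata["sample_type"] == "reference"]
        counts = ref["rh_purge"].map(assign_rh_subgroup).value_counts()
        assert counts.to_dict() == {"20-30": 10, "30-40": 12, "40-50": 11}


class TestMannWhitney:
    def test_fully_separated_triples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_near_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.95

    @pytest.mark.parametrize("m,n", [(m, n) for m in range(2, 7) for n in range(m, 7)])
    def test_exact_p_matches_full_enumeration(self, m, n):
        rng = np.random.default_rng(100 * m + n)
        for _ in range(3):
            x = rng.permutation(np.arange(1.0, m + n + 1))[:m]
            y = np.setdiff1d(np.arange(1.0, m + n + 1), x)
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    def test_swap_symmetry(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(size=rng.integers(3, 15))
            assert mann_whitney_u(x, y).p_value == pytest.approx(
                mann_whitney_u(y, x).p_value, rel=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_null_rejection_rate_is_calibrated(self):
        """Under identical Gaussian groups (the simulator's noise model) the
        rejection rate at alpha = 0.01 matches the nominal level within the
        binomial 95% interval over 2000 replicates."""
        rng = np.random.default_rng(2024)
        alpha = 0.01
        n_rep = 2000
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(0.0, 5e-4, size=20)
            y = rng.normal(0.0, 5e-4, size=20)
            if mann_whitney_u(x, y).p_value < alpha:
                rejections += 1
        rate = rejections / n_rep
        half_width = 1.96 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= half_width


class TestKruskalWallis:
    def test_identical_constants_give_h_zero(self):
        res = kruskal_wallis([5.0, 5.0], [5.0, 5.0, 5.0], [5.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_h_on_separated_ranks(self):
        # ranks 1-9 in three fully separated groups:
        # H = 12/(9*10) * 3*[(2-5)^2 + (5-5)^2 + (8-5)^2] = 7.2
        res = kruskal_wallis([1, 2, 3], [10, 11, 12], [20, 21, 22])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)

    def test_two_group_kw_agrees_with_mwu_decision(self, rng):
        alpha = 0.01
        for shift in (0.0, 0.0, 2.0, 2.0, 0.5):
            x = rng.normal(0.0, 1.0, size=25)
            y = rng.normal(shift, 1.0, size=25)
            p_kw = kruskal_wallis(x, y).p_value
            p_mwu = mann_whitney_u(x, y).p_value
            borderline = alpha / 2 < min(p_kw, p_mwu) < alpha * 2
            assert (p_kw < alpha) == (p_mwu < alpha) or borderline

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])


class TestBonferroni:
    def test_multiplication_and_cap(self):
        assert bonferroni([0.004], m=3) == [pytest.approx(0.012)]
        assert bonferroni([0.5], m=3) == [1.0]
        assert bonferroni([0.2, 0.3]) == [pytest.approx(0.4), pytest.approx(0.6)]

    def test_identity_for_single_test(self):
        assert bonferroni([0.123], m=1) == [pytest.approx(0.123)]

    def test_never_decreases_and_monotone_in_m(self, rng):
        ps = rng.uniform(size=20).tolist()
        adj3 = bonferroni(ps, m=20)
        adj5 = bonferroni(ps, m=40)
        assert all(a >= p for a, p in zip(adj3, ps))
        assert all(b >= a for a, b in zip(adj3, adj5))

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni([0.1], m=0)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestSubgroupAnalysis:
    def test_offset_features_depend_on_rh_bin_everywhere(
        self, offset_table, study_metadata
    ):
        sg = subgroup_analysis(offset_table, study_metadata,
                               method="start_point_offset")
        kw = sg.results[(sg.results["test"] == "kruskal_wallis")
                        & (sg.results["comparison"] == "breath:rh_bins")]
        assert len(kw) == 33  # 3 channels x 11 areas
        assert (kw["p"] < 0.01).all()

    def test_breath_vs_reference_significant_in_subset_under_minmax(
        self, minmax_table, study_metadata
    ):
        sg = subgroup_analysis(minmax_table, study_metadata, method="min_max")
        between = sg.results[
            sg.results["comparison"].str.startswith("breath vs reference")
        ]
        per_area = between.groupby(["channel", "area"])["significant"].all()
        assert per_area.any()  # some areas discriminate in every RH bin

    def test_family_size_is_recorded(self, offset_table, study_metadata):
        sg = subgroup_analysis(offset_table, study_metadata,
                               method="start_point_offset")
        mwu = sg.results[sg.results["test"] == "mann_whitney_u"]
        assert (mwu["m"] == 9).all()  # 3 within-breath + 3 within-ref + 3 between
        assert (mwu["p_adj"] >= mwu["p"]).all()

    def test_representative_area_reported_per_channel(
        self, offset_table, study_metadata
    ):
        sg = subgroup_analysis(offset_table, study_metadata,
                               method="start_point_offset")
        assert set(sg.representative_areas) == {1, 2, 3}
        assert all(a in set("ABCDEFGHIJK") for a in sg.representative_areas.values())

    def test_shuffled_labels_are_mostly_non_significant(
        self, offset_table, study_metadata, rng
    ):
        n_sig = n_tot = 0
        for _ in range(5):
            shuffled = study_metadata.copy()
            shuffled["rh_purge"] = rng.permutation(shuffled["rh_purge"].to_numpy())
            sg = subgroup_analysis(offset_table, shuffled,
                                   method="start_point_offset")
            kw = sg.results[sg.results["test"] == "kruskal_wallis"]
            n_sig += int((kw["p"] < 0.01).sum())
            n_tot += len(kw)
        assert n_sig / n_tot < 0.05
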
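"""Count-table processing, rank-frequency statistics and lineage arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tumorclones.clonestats import (
    bonferroni_adjust,
    build_master_list,
    collapse_replicates,
    doublings,
    fit_power_law,
    generation_time,
    mutation_free_probability,
    overlap_fisher,
    rank_frequency,
    rpm_normalize,
    shannon_entropy,
    spearman_corr,
)
from tumorclones.dynamics import SimulationParams, predicted_rank_frequency, simulate
from tumorclones.tables import CountTable


class TestRpmNormalize:
    def test_two_equal_counts(self):
        t = CountTable(pd.DataFrame({"s_rep1": [1, 1]}, index=["a", "b"]))
        out = rpm_normalize(t)
        np.testing.assert_allclose(out.data["s_rep1"], [5e5, 5e5])

    def test_million_deep_column_unchanged(self):
        t = CountTable(pd.DataFrame({"s_rep1": [750_000, 250_000]}, index=["a", "b"]))
        out = rpm_normalize(t)
        np.testing.assert_allclose(out.data["s_rep1"], [750_000, 250_000])

    def test_hand_fixture(self):
        t = CountTable(pd.DataFrame({"s_rep1": [3, 1, 0]}, index=list("abc")))
        np.testing.assert_allclose(rpm_normalize(t).data["s_rep1"], [750_000, 250_000, 0])

    def test_zero_depth_rejected(self):
        t = CountTable(pd.DataFrame({"s_rep1": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="zero-depth"):
            rpm_normalize(t)


class TestMasterList:
    def test_hand_fixture_exact_set(self, t0_fixture_table):
        # rule: strictly above 10 RPM in >= 2 of 4 replicates
        master = build_master_list(rpm_normalize(t0_fixture_table))
        assert master == {"bcA", "bcD", "bcFill"}

    def test_raw_input_warns_and_normalizes(self, t0_fixture_table):
        with pytest.warns(UserWarning, match="normaliz"):
            master = build_master_list(t0_fixture_table)
        assert master == {"bcA", "bcD", "bcFill"}

    def test_single_replicate_hit_excluded(self, t0_fixture_table):
        assert "bcB" not in build_master_list(rpm_normalize(t0_fixture_table))

    def test_needs_enough_replicates(self):
        t = CountTable(pd.DataFrame({"T0_rep1": [5]}, index=["a"]), units="rpm")
        with pytest.raises(ValueError, match="replicate"):
            build_master_list(t, min_replicates=2)


class TestCollapseReplicates:
    def _rpm(self, frame):
        return CountTable(frame, units="rpm")

    def test_identical_replicates_unchanged(self):
        t = self._rpm(pd.DataFrame({"T_rep1": [10.0, 5.0], "T_rep2": [10.0, 5.0]},
                                   index=["a", "b"]))
        out = collapse_replicates(t, {"a", "b"})
        np.testing.assert_allclose(out.data["T"], [10.0, 5.0])

    def test_mean_of_two(self):
        t = self._rpm(pd.DataFrame({"T_rep1": [10.0], "T_rep2": [30.0]}, index=["a"]))
        assert collapse_replicates(t, {"a"}).data["T"].iloc[0] == pytest.approx(20.0)

    def test_tumor_only_barcode_dropped(self):
        t = self._rpm(pd.DataFrame({"T_rep1": [10.0, 99.0], "T_rep2": [10.0, 99.0]},
                                   index=["known", "artifact"]))
        out = collapse_replicates(t, {"known"})
        assert list(out.data.index) == ["known"]

    def test_missing_replicate_rejected(self):
        t = self._rpm(pd.DataFrame(
            {"T1_rep1": [1.0], "T1_rep2": [1.0], "T2_rep1": [1.0]}, index=["a"]))
        with pytest.raises(ValueError, match="missing replicate"):
            collapse_replicates(t, {"a"})


class TestRankFrequency:
    def test_simple_pair(self):
        ra = rank_frequency([4, 1])
        np.testing.assert_array_equal(ra.ranks, [1, 2])
        np.testing.assert_allclose(ra.frequencies, [0.8, 0.2])

    def test_uniform(self):
        ra = rank_frequency(np.ones(7))
        np.testing.assert_allclose(ra.frequencies, np.full(7, 1 / 7))

    def test_zeros_dropped_and_sorted_input_preserved(self):
        f = np.array([0.5, 0.25, 0.125, 0.0, 0.125])
        ra = rank_frequency(f, ids=list("abcde"))
        assert len(ra) == 4
        assert ra.ids[0] == "a"

    def test_ties_broken_by_id(self):
        ra = rank_frequency([1.0, 1.0, 2.0], ids=["z", "a", "m"])
        assert ra.ids == ["m", "a", "z"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rank_frequency([0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30))
    def test_entropy_invariant_to_input_order(self, values):
        h1 = shannon_entropy(rank_frequency(values).frequencies)
        h2 = shannon_entropy(rank_frequency(values[::-1]).frequencies)
        assert h1 == pytest.approx(h2, rel=1e-9)


class TestPowerLawFit:
    @pytest.mark.parametrize("method", ["nls", "loglog"])
    def test_exact_zipf(self, method):
        r = np.arange(1, 101)
        f = 1.0 / r
        ra = rank_frequency(f)
        fit = fit_power_law(ra, method=method)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.beta == pytest.approx(ra.frequencies[0], rel=1e-6)

    @pytest.mark.parametrize("method", ["nls", "loglog"])
    def test_exact_half_exponent(self, method):
        r = np.arange(1, 51)
        ra = rank_frequency(2.0 * r**-0.5)
        assert fit_power_law(ra, method=method).alpha == pytest.approx(0.5, abs=1e-6)

    def test_recovers_zipf_from_model_rank_frequency(self):
        # frequencies generated from the analytic law at r << B are Zipf
        B = 10_000
        r = np.arange(1, 501)
        f = predicted_rank_frequency(r, B, n_star=100.0, N_total=1e6)
        fit = fit_power_law(rank_frequency(f), method="loglog")
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_needs_three_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_power_law(rank_frequency([2.0, 1.0]))


class TestShannonEntropy:
    def test_single_clone(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_uniform_is_log_k(self):
        assert shannon_entropy(np.full(32, 1 / 32), log_base=2) == pytest.approx(5.0)

    def test_half_half_nats(self):
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(math.log(2))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            shannon_entropy([0.5, 0.2])


class TestAssociationTests:
    def test_fisher_against_enumeration(self):
        # table (a=3,b=1,c=1,d=3): enumerate all tables with the same margins
        a, b, c, d = 3, 1, 1, 3
        p_scipy = overlap_fisher({1, 2, 3, 9}, {1, 2, 3, 7}, 8)
        row1, col1, n = a + b, a + c, a + b + c + d
        p_obs = sps.hypergeom.pmf(a, n, row1, col1)
        p_sum = sum(
            sps.hypergeom.pmf(x, n, row1, col1)
            for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if sps.hypergeom.pmf(x, n, row1, col1) <= p_obs * (1 + 1e-9)
        )
        assert p_scipy == pytest.approx(p_sum, rel=1e-9)

    def test_identical_sets_maximally_overlapping(self):
        s = set(range(5))
        assert 0 < overlap_fisher(s, s, 5) <= 1.0

    def test_universe_must_cover_union(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_fisher({1, 2}, {3, 4}, 3)

    def test_spearman_perfect_monotone(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [10, 20, 25, 80])
        assert rho == pytest.approx(1.0)

    def test_bonferroni(self):
        assert bonferroni_adjust([0.01, 0.4, 0.9]) == [0.03, 1.0, 1.0]


class TestLineageArithmetic:
    def test_mutation_free_probability_worked_example(self):
        # E. coli rate 0.001/genome/generation, single cell -> 2e9 cells
        assert round(mutation_free_probability(0.001, 2e9), 2) == 0.97

    def test_no_mutations_certain_without_rate(self):
        assert mutation_free_probability(0.0, 1e12) == 1.0

    def test_one_generation(self):
        assert mutation_free_probability(0.001, 2) == pytest.approx(0.999)

    def test_doublings_of_leading_clone(self):
        assert round(doublings(2.5e8)) == 28
        assert doublings(2.5e8) == pytest.approx(27.897, abs=1e-3)

    def test_generation_time_of_leading_clone(self):
        # 24 h over ~28 divisions is ~50 min at the study's rounding
        assert generation_time(2.5e8, 24.0) == pytest.approx(51.6, abs=0.1)
        assert generation_time(2.0, 1.0) == pytest.approx(60.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            doublings(0.5)
        with pytest.raises(ValueError):
            mutation_free_probability(1.0, 10)


class TestInVitroLimit:
    def test_demographic_growth_preserves_frequency_structure(self, small_library):
        # batch growth with sqrt(N) demographic noise from a narrow inoculum:
        # rank correlation of pre/post log-frequencies > 0.9, entropy within 5%
        f = small_library.frequencies
        init = f * 5e5  # ~500 cells per barcode
        params = SimulationParams(
            mode="demographic", D=1e-3, s0=5e6, k=1e3, horizon=3.0,
            resource_policy="substep",
        )
        traj = simulate(params, init, seed=4)
        final = traj.final_abundances
        assert traj.total_cfu[-1] > 3 * traj.total_cfu[0]  # real growth happened
        rho, _ = spearman_corr(np.log(init), np.log(final))
        assert rho > 0.9
        h_pre = shannon_entropy(init / init.sum())
        h_post = shannon_entropy(final / final.sum())
        assert abs(h_post - h_pre) / h_pre < 0.05
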
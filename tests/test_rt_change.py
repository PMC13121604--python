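"""Window significance tests, BH control, stitching and allelic advance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rtswitch import (
    allelic_rt_advance,
    bh_qvalues,
    call_switch_regions,
    monte_carlo_window_test,
    significance_vs_wt,
    ttest_window_test,
)
from rtswitch.rt_change import _null_pool, _stack

from test_rt_profile import make_profile


def replicate_profiles(matrix, bin_size=50_000, mask=None):
    return [make_profile(row, bin_size=bin_size, mask=mask) for row in np.atleast_2d(matrix)]


class TestBH:
    def test_hand_computed_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_qvalues(np.array([0.2])).tolist() == [0.2]
        assert bh_qvalues(np.array([1.0, 1.0])).tolist() == [1.0, 1.0]
        assert bh_qvalues(np.array([])).size == 0

    def test_nan_propagates_without_affecting_m(self):
        q = bh_qvalues(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], [0.02, 0.02])

    def test_matches_bruteforce_and_statsmodels(self, rng):
        for _ in range(30):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 200)))
            q = bh_qvalues(p)
            brute = np.array(
                [
                    min(
                        min(
                            len(p) * pj / (np.sum(p <= pj))
                            for pj in p
                            if pj >= pi
                        ),
                        1.0,
                    )
                    for pi in p
                ]
            )
            assert np.allclose(q, brute, atol=1e-12)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestMonteCarlo:
    def test_strong_signal_hits_p_floor(self, rng):
        a = replicate_profiles(rng.normal(0, 0.1, size=(3, 50)))
        b_vals = rng.normal(0, 0.1, size=(3, 50))
        b_vals[:, 10] += 50.0
        b = replicate_profiles(b_vals)
        out = monte_carlo_window_test(a, b, n_mc=1000, seed=0)
        assert out.loc[10, "p"] == pytest.approx(1.0 / 1001)

    def test_zero_difference_gives_p_one(self):
        vals = np.tile(np.linspace(-1, 1, 20), (2, 1))
        out = monte_carlo_window_test(
            replicate_profiles(vals), replicate_profiles(vals), n_mc=500, seed=0
        )
        assert (out["p"] == 1.0).all()

    def test_matches_exhaustive_enumeration(self, rng):
        n_mc = 10_000
        for case in range(20):
            a = replicate_profiles(rng.normal(0, 1, size=(2, 30)))
            b = replicate_profiles(rng.normal(0.5, 1, size=(2, 30)))
            out = monte_carlo_window_test(a, b, n_mc=n_mc, seed=case)
            amat, _ = _stack(a)
            bmat, _ = _stack(b)
            pool = np.abs(_null_pool(amat, bmat)) * np.sqrt((1 / 2 + 1 / 2) / 2)
            obs = np.abs(np.nanmean(bmat, 0) - np.nanmean(amat, 0))
            for w in range(5):
                tail = np.mean(pool >= obs[w])
                exact = (1 + n_mc * tail) / (1 + n_mc)
                sd = np.sqrt(max(tail * (1 - tail), 1e-12) / n_mc)
                assert abs(out.loc[w, "p"] - exact) <= 3 * sd + 1e-9

    def test_single_replicates_error(self):
        a = replicate_profiles(np.zeros((1, 10)))
        b = replicate_profiles(np.ones((1, 10)))
        with pytest.raises(ValueError, match="null pool"):
            monte_carlo_window_test(a, b, n_mc=100, seed=0)

    def test_nonpositive_n_mc_rejected(self):
        a = replicate_profiles(np.zeros((2, 10)))
        with pytest.raises(ValueError, match="n_mc"):
            monte_carlo_window_test(a, a, n_mc=0, seed=0)

    def test_p_decreases_with_more_draws_for_strong_signal(self, rng):
        a = replicate_profiles(rng.normal(0, 0.1, size=(2, 40)))
        b_vals = rng.normal(0, 0.1, size=(2, 40))
        b_vals[:, 5] += 10.0
        b = replicate_profiles(b_vals)
        p_small = monte_carlo_window_test(a, b, n_mc=100, seed=3).loc[5, "p"]
        p_large = monte_carlo_window_test(a, b, n_mc=10_000, seed=3).loc[5, "p"]
        assert 0 < p_large < p_small


class TestTTest:
    def test_identical_vectors_are_null(self):
        vals = np.array([[0.1, 0.2], [0.3, 0.1], [0.2, 0.4]])
        out = ttest_window_test(replicate_profiles(vals), replicate_profiles(vals), paired=True)
        assert (out["t"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_zero_variance_sentinel(self):
        a = replicate_profiles(np.zeros((4, 3)))
        b = replicate_profiles(np.ones((4, 3)))
        out = ttest_window_test(a, b, paired=True)
        assert out["p"].isna().all()
        assert np.isnan(bh_qvalues(out["p"].to_numpy())).all()

    def test_paired_matches_closed_form(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 9))
            x = rng.normal(size=(n, 1))
            y = rng.normal(0.5, 1.2, size=(n, 1))
            out = ttest_window_test(
                replicate_profiles(x), replicate_profiles(y), paired=True
            )
            d = (y - x).ravel()
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), n - 1)
            assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)
            assert out.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_welch_matches_scipy(self, rng):
        for _ in range(50):
            x = rng.normal(size=(4, 1))
            y = rng.normal(1.0, 2.0, size=(5, 1))
            out = ttest_window_test(replicate_profiles(x), replicate_profiles(y))
            ref = stats.ttest_ind(y.ravel(), x.ravel(), equal_var=False)
            assert out.loc[0, "t"] == pytest.approx(ref.statistic, abs=1e-10)
            assert out.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_center_removes_constant_offset(self, rng):
        a = replicate_profiles(rng.normal(0, 0.05, size=(4, 200)))
        b = replicate_profiles(rng.normal(0, 0.05, size=(4, 200)) - 0.5)
        raw = ttest_window_test(a, b)
        centered = ttest_window_test(a, b, center=True)
        assert (raw["p"] < 0.01).mean() > 0.5
        assert (centered["p"] < 0.01).mean() < 0.05


class TestCallSwitchRegions:
    @staticmethod
    def results(rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "delta_rt", "p", "q", "direction"]
        )

    def test_no_significant_windows(self):
        res = self.results([("c", 0, 50_000, 1.0, 0.5, 0.9, "advance")])
        assert call_switch_regions(res).empty

    def test_gap_merging_same_direction(self):
        res = self.results(
            [
                ("c", 0, 50_000, 1.0, 1e-5, 1e-4, "advance"),
                ("c", 300_000, 350_000, 1.2, 1e-5, 1e-4, "advance"),
            ]
        )
        out = call_switch_regions(res, q_cut=0.001, gap_bp=300_000)
        assert out[["chrom", "start", "end"]].values.tolist() == [["c", 0, 350_000]]
        assert out.loc[0, "mean_delta_rt"] == pytest.approx(1.1)
        assert out.loc[0, "n_windows"] == 2

    def test_directions_never_merge(self):
        res = self.results(
            [
                ("c", 0, 50_000, 1.0, 1e-5, 1e-4, "advance"),
                ("c", 100_000, 150_000, -1.0, 1e-5, 1e-4, "delay"),
                ("c", 200_000, 250_000, 1.0, 1e-5, 1e-4, "advance"),
            ]
        )
        out = call_switch_regions(res, q_cut=0.001, gap_bp=300_000)
        assert len(out) == 2
        assert set(out["direction"]) == {"advance", "delay"}
        adv = out[out["direction"] == "advance"].iloc[0]
        assert (adv["start"], adv["end"]) == (0, 250_000)


class TestAllelicAdvance:
    def test_baseline_normalized_arithmetic(self):
        region = ("c", 0, 100_000)
        mean, per_bin = allelic_rt_advance(
            make_profile([1.0, 1.0, 0.0, 0.0]),
            make_profile([0.0, 0.0, 0.0, 0.0]),
            make_profile([0.2, 0.2, 0.0, 0.0]),
            make_profile([0.0, 0.0, 0.0, 0.0]),
            region,
        )
        assert mean == pytest.approx(0.8)
        assert per_bin[:2] == pytest.approx([0.8, 0.8])

    def test_mutant_equals_wt_gives_zero(self, rng):
        vals = rng.normal(size=8)
        p = make_profile(vals)
        mean, _ = allelic_rt_advance(p, p, p, p, ("c", 0, 400_000))
        assert mean == pytest.approx(0.0)

    def test_all_masked_region_errors(self):
        mask = [False] * 4
        p = make_profile(np.ones(4), mask=mask)
        with pytest.raises(ValueError, match="masked"):
            allelic_rt_advance(p, p, p, p, ("c", 0, 200_000))


class TestProperties:
    def test_larger_effect_never_less_significant(self, rng):
        """Median window p over a planted region decreases with effect size."""
        n_bins = 300
        base = rng.normal(0, 0.2, size=(4, n_bins))
        medians = []
        for effect in (0.5, 1.0, 2.0, 4.0):
            b_vals = rng.normal(0, 0.2, size=(4, n_bins))
            b_vals[:, 100:110] += effect
            out = monte_carlo_window_test(
                replicate_profiles(base), replicate_profiles(b_vals), n_mc=2000, seed=9
            )
            medians.append(out.loc[100:109, "p"].median())
        assert all(a >= b for a, b in zip(medians, medians[1:]))

    def test_null_flag_rate_calibrated(self, rng):
        a = replicate_profiles(rng.normal(0, 0.2, size=(4, 2000)))
        b = replicate_profiles(rng.normal(0, 0.2, size=(4, 2000)))
        out = significance_vs_wt(b, a, n_mc=5000, seed=2)
        frac = out["significant"].mean()
        assert 0.004 < frac < 0.022
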
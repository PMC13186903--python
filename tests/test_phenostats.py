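"""Exact tests, ddCt, fibrosis summaries and AF endpoints."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from haplostrat.phenostats import (
    CONTROL,
    IHF,
    PhenotypeTable,
    _brute_force_mw_pvalue,
    af_endpoints,
    ddct_fold_change,
    fibrosis_heterogeneity,
    fisher_exact_2x2,
    mann_whitney_u,
    pearson_corr,
)


def enumerate_fisher_two_sided(table):
    """Oracle: exhaustive hypergeometric enumeration over the margin-fixed
    family of tables (exact rational arithmetic via math.comb)."""
    import math
    from fractions import Fraction

    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)
        assert res.mode == "exact"

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([5, 7, 7, 9], [5, 7, 7, 9])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (4, 2)])
    def test_exact_equals_brute_force_enumeration_with_ties(self, rng, n1, n2):
        for _ in range(20):
            x = rng.integers(0, 4, size=n1)  # small range forces ties
            y = rng.integers(0, 4, size=n2)
            res = mann_whitney_u(x, y, mode="exact")
            assert res.pvalue == pytest.approx(
                _brute_force_mw_pvalue(x, y), abs=1e-12
            )

    def test_auto_switches_to_exact_at_small_n(self):
        assert mann_whitney_u([1] * 10, [2] * 10, mode="auto").mode == "exact"
        assert mann_whitney_u([1] * 11, [2] * 10, mode="auto").mode == "approximate"

    def test_approximate_close_to_exact_at_moderate_n(self, rng):
        x = rng.normal(0, 1, size=10)
        y = rng.normal(0.5, 1, size=10)
        p_exact = mann_whitney_u(x, y, mode="exact").pvalue
        p_approx = mann_whitney_u(x, y, mode="approximate").pvalue
        assert p_approx == pytest.approx(p_exact, abs=0.03)

    def test_agrees_with_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        res = mann_whitney_u(x, y, mode="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestFisherExact:
    def test_hand_enumerated_3113(self):
        res = fisher_exact_2x2([[3, 1], [1, 3]])
        assert res.pvalue == pytest.approx(34 / 70, abs=1e-12)

    def test_hand_enumerated_2002(self):
        res = fisher_exact_2x2([[2, 0], [0, 2]])
        assert res.pvalue == pytest.approx(2 / 6, abs=1e-12)
        assert res.statistic == float("inf")

    def test_degenerate_margin_p_one(self):
        assert fisher_exact_2x2([[0, 5], [0, 7]]).pvalue == 1.0

    def test_matches_enumeration_all_small_margins(self):
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d == 0:
                continue
            if max(a + b, c + d, a + c, b + d) > 12:
                continue
            table = [[a, b], [c, d]]
            got = fisher_exact_2x2(table).pvalue
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                assert got == 1.0
                continue
            assert got == pytest.approx(
                enumerate_fisher_two_sided(table), rel=1e-9
            ), table

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            got = fisher_exact_2x2(t).pvalue
            ref = sps.fisher_exact(t)[1]
            assert got == pytest.approx(ref, rel=1e-7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_corr(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestFibrosisHeterogeneity:
    def test_uniform_images_zero_spread(self):
        out = fibrosis_heterogeneity([7.0] * 10, [7.0] * 10)
        assert out["la_diff"] == 0.0 and out["la_sd"] == 0.0

    def test_hand_arithmetic(self):
        out = fibrosis_heterogeneity([2, 4, 10], [1, 1, 1])
        assert out["la_diff"] == 8.0
        assert out["la_mean"] == pytest.approx(16 / 3)

    def test_single_image_rejected(self):
        with pytest.raises(ValueError, match="images"):
            fibrosis_heterogeneity([5.0], [5.0, 6.0])


class TestDdct:
    def test_control_sample_at_control_mean_has_fold_one(self):
        ct = np.array([20.0, 21.0, 22.0])
        ref = np.array([15.0, 16.0, 17.0])  # dct = 5 everywhere
        grp = np.array([CONTROL, CONTROL, IHF], dtype=object)
        res = ddct_fold_change(ct, ref, grp, CONTROL)
        np.testing.assert_allclose(res["fold"], 1.0)

    def test_one_cycle_decrease_doubles_fold(self):
        ct = np.array([20.0, 20.0, 19.0])
        ref = np.array([15.0, 15.0, 15.0])
        grp = np.array([CONTROL, CONTROL, IHF], dtype=object)
        res = ddct_fold_change(ct, ref, grp, CONTROL)
        assert res["fold"].iloc[2] == pytest.approx(2.0)

    def test_control_mean_ddct_exactly_zero(self, rng):
        ct = rng.uniform(18, 28, size=12)
        ref = rng.uniform(14, 18, size=12)
        grp = np.array([CONTROL] * 6 + [IHF] * 6, dtype=object)
        res = ddct_fold_change(ct, ref, grp, CONTROL)
        assert res.loc[res["group"] == CONTROL, "ddct"].mean() == pytest.approx(
            0.0, abs=1e-12
        )

    def test_sample_wise_ct_shift_cancels(self, rng):
        ct = rng.uniform(18, 28, size=8)
        ref = rng.uniform(14, 18, size=8)
        shift = rng.uniform(-3, 3, size=8)
        grp = np.array([CONTROL] * 4 + [IHF] * 4, dtype=object)
        base = ddct_fold_change(ct, ref, grp, CONTROL)
        shifted = ddct_fold_change(ct + shift, ref + shift, grp, CONTROL)
        np.testing.assert_allclose(base["fold"], shifted["fold"], rtol=1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            ddct_fold_change(
                np.array([20.0, 21.0]),
                np.array([15.0, np.nan]),
                np.array([CONTROL, IHF], dtype=object),
                CONTROL,
            )


def _af_table(rows):
    recs = []
    for animal, treatment, episodes, n_stims in rows:
        recs.append(
            {
                "animal_id": animal,
                "treatment": treatment,
                "variable": "n_burst_stims",
                "value": float(n_stims),
            }
        )
        for k, dur in enumerate(episodes):
            recs.append(
                {
                    "animal_id": animal,
                    "treatment": treatment,
                    "variable": "af_episode_s",
                    "value": float(dur),
                    "stim": k,
                }
            )
    return PhenotypeTable(pd.DataFrame.from_records(recs))


class TestAfEndpoints:
    def test_strict_threshold_and_per_stim_fraction(self):
        pt = _af_table([("p1", IHF, [12.0, 4.0], 6)])
        per_animal, _ = af_endpoints(pt)
        row = per_animal.iloc[0]
        assert bool(row["inducible"])
        assert row["per_stim_fraction"] == pytest.approx(1 / 6)

    def test_boundary_episode_not_inducible(self):
        pt = _af_table([("p1", IHF, [10.0], 6)])
        per_animal, _ = af_endpoints(pt)
        assert not bool(per_animal.iloc[0]["inducible"])

    def test_inducibility_monotone_in_threshold(self):
        pt = _af_table([("p1", IHF, [8.0, 12.0, 20.0], 6)])
        fractions = [
            af_endpoints(pt, episode_min_s=t)[0].iloc[0]["per_stim_fraction"]
            for t in (5.0, 10.0, 15.0, 25.0)
        ]
        assert fractions == sorted(fractions, reverse=True)
        assert all(0 <= f <= 1 for f in fractions)

    def test_more_episodes_than_stims_rejected(self):
        pt = _af_table([("p1", IHF, [12.0, 13.0, 14.0], 2)])
        with pytest.raises(ValueError, match="exceed"):
            af_endpoints(pt)

    def test_group_contrasts_run_fisher_at_both_levels(self):
        rows = [(f"i{k}", IHF, [15.0], 6) for k in range(5)]
        rows += [(f"c{k}", CONTROL, [], 6) for k in range(5)]
        pt = _af_table(rows)
        _, tests = af_endpoints(pt, groups={a: "G" for a, *_ in rows})
        assert set(tests["level"]) == {"animal", "stimulation"}
        animal_p = tests.loc[tests["level"] == "animal", "p"].iloc[0]
        assert animal_p == pytest.approx(
            fisher_exact_2x2([[5, 0], [0, 5]]).pvalue
        )
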
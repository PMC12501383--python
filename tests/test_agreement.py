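"""MOS aggregation, histograms, significance tests, weighted Fleiss' kappa."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emip.agreement import (
    GainResult,
    RatingTable,
    enumerate_group_pairs,
    group3_kappa,
    histogram_diff,
    histogram_mos,
    inter_gain_rater_variance,
    interpret_kappa,
    intra_kappa,
    jackknife_rater_variance,
    kappa_compare,
    kappa_gain,
    linear_weights,
    mean_diff_test,
    median_diff_test,
    mos,
    mos_differences,
    weighted_fleiss_kappa,
)


def table(ratings, repeats=None, method="MIP"):
    ratings = np.asarray(ratings, dtype=float)
    n, r = ratings.shape
    return RatingTable(
        scan_ids=[f"s{i}" for i in range(n)],
        rater_ids=[f"r{j}" for j in range(r)],
        ratings=ratings,
        repeats=None if repeats is None else np.asarray(repeats, dtype=float),
        method=method,
    )


def kappa_oracle(scores, weights):
    """Independent brute-force weighted Fleiss kappa (pairs + pooled marginals)."""
    scores = np.asarray(scores, dtype=float)
    lv = list(weights.levels)
    d_sum, n_scans = 0.0, 0
    pooled = []
    for row in scores:
        vals = row[~np.isnan(row)]
        if vals.size < 2:
            continue
        pairs = [
            weights.w[lv.index(a), lv.index(b)]
            for a, b in itertools.permutations(vals, 2)
        ]
        d_sum += np.mean(pairs)
        n_scans += 1
        pooled.extend(vals)
    D_o = d_sum / n_scans
    pooled = np.asarray(pooled)
    pi = np.array([(pooled == v).mean() for v in lv])
    D_e = float(pi @ weights.w @ pi)
    return 1.0 if D_e == 0 else 1.0 - D_o / D_e


class TestMos:
    def test_unanimous(self):
        t = table(np.full((3, 8), 3.0))
        assert np.all(mos(t).values == 3.0)

    def test_mixed_ratings_mean(self):
        t = table([[1, 2, 2, 3, 3, 3, 4, 4]])
        assert mos(t).values[0] == pytest.approx(2.75)

    def test_two_stage_repeat_averaging(self):
        ratings = np.array([[2.0] + [3.0] * 7])
        repeats = np.full((1, 8), np.nan)
        repeats[0, 0] = 3.0
        t = table(ratings, repeats)
        # rater 0 contributes (2+3)/2 = 2.5 -> MOS = (2.5 + 7*3)/8
        assert mos(t).values[0] == pytest.approx(2.9375)

    def test_empty_scan_excluded_with_warning(self):
        ratings = np.array([[3.0, 3.0], [np.nan, np.nan]])
        t = table(ratings)
        with pytest.warns(RuntimeWarning, match="excluded"):
            m = mos(t)
        assert list(m.index) == ["s0"]


class TestMosDifferences:
    def test_identical_tables(self):
        t = table(np.tile([2, 3, 3, 4], (5, 1)))
        d, summary = mos_differences(t, t)
        assert np.all(d.values == 0)
        assert summary["frac_substantial_positive"] == 0.0
        assert summary["frac_substantial_negative"] == 0.0

    def test_exact_half_point_shift(self):
        # a genuine +0.5 MOS shift: raise two of four raters by one level
        base = np.tile([2.0, 2, 3, 3], (6, 1))
        shifted = base.copy()
        shifted[:, :2] += 1.0
        d, summary = mos_differences(table(shifted), table(base))
        assert np.all(d.values == pytest.approx(0.5))
        assert summary["mean"] == pytest.approx(0.5)
        assert summary["frac_substantial_positive"] == 1.0

    def test_mismatched_scans_error(self):
        a = table(np.full((3, 2), 3.0))
        b = table(np.full((4, 2), 3.0))
        with pytest.raises(ValueError, match="scan sets differ"):
            mos_differences(a, b)

    def test_simulated_quarter_point_shift_recovered(self):
        rng = np.random.default_rng(42)
        n = 1725
        base = rng.integers(1, 4, size=(n, 8)).astype(float)  # 1..3
        bump = rng.random((n, 8)) < 0.25
        d, summary = mos_differences(table(base + bump), table(base))
        se = d.values.std(ddof=1) / np.sqrt(n)
        assert abs(summary["mean"] - 0.25) < 3 * se


class TestHistograms:
    def test_boundary_value_goes_to_left_bin(self):
        h = histogram_mos([2.0], width=0.125)
        hit = np.nonzero(h.counts)[0][0]
        assert h.edges[hit + 1] == pytest.approx(2.0)  # bin ending at 2.0

    def test_single_value_single_bin(self):
        h = histogram_mos([3.3] * 7)
        assert (h.counts > 0).sum() == 1
        assert h.percent.max() == pytest.approx(100.0)

    def test_uniform_grid_matches_bruteforce(self):
        vals = np.round(np.linspace(1.0, 4.0, 25), 6)
        h = histogram_mos(vals, width=0.125)
        for lo, hi, c in zip(h.edges[:-1], h.edges[1:], h.counts):
            brute = sum(1 for v in vals if lo < v <= hi)
            assert c == brute
        assert h.counts.sum() == vals.size

    def test_diff_histogram_has_zero_centered_bin(self):
        h = histogram_diff([0.0, 0.1, -0.1, 0.5])
        centers = 0.5 * (h.edges[:-1] + h.edges[1:])
        assert np.any(np.abs(centers) < 1e-9)
        assert h.counts.sum() == 4


class TestMeanDiffTest:
    def test_identical_samples(self):
        a = np.array([2.0, 3.0, 3.0, 4.0] * 5)
        res = mean_diff_test(a, a.copy())
        assert res["p"] == pytest.approx(1.0)
        assert res["ci_low"] <= 0.0 <= res["ci_high"]

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(3.0, 0.1, 100)
        res = mean_diff_test(a + 1.0, a)
        assert res["p"] < 1e-4

    def test_matches_closed_form(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1.2, 55)
        res = mean_diff_test(a, b, alpha=0.05)
        n1, n2 = 40, 55
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res["t"] == pytest.approx(t_manual, abs=1e-10)
        from scipy import stats as sps

        assert res["p"] == pytest.approx(
            2 * sps.t.sf(abs(t_manual), n1 + n2 - 2), abs=1e-10
        )

    def test_right_tailed_variant_exposed(self, rng):
        a = rng.normal(3.2, 0.5, 60)
        b = rng.normal(3.0, 0.5, 60)
        res = mean_diff_test(a, b, alternative="greater")
        assert res["alternative"] == "greater"
        assert 0 <= res["p"] <= 1


class TestMedianDiffTest:
    def test_symmetric_differences_not_significant(self, rng):
        d = np.concatenate([rng.normal(0, 1, 250)])
        res = median_diff_test(d, seed=1)
        assert res["p"] > 0.01

    def test_constant_positive_shift_degenerate_bootstrap(self):
        d = np.full(30, 0.3)
        res = median_diff_test(d, seed=2)
        assert res["p"] < 1e-5
        assert res["ci_low"] == pytest.approx(0.3)
        assert res["ci_high"] == pytest.approx(0.3)

    def test_bootstrap_coverage_at_nominal_level(self):
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            d = rng.normal(0.4, 1.0, 120)  # true median 0.4
            res = median_diff_test(d, n_boot=400, seed=i)
            hits += res["ci_low"] <= 0.4 <= res["ci_high"]
        assert hits >= 88  # ~95% nominal with simulation slack


class TestWeights:
    def test_native_scale(self):
        w = linear_weights([1, 2, 3, 4])
        assert w.w[0, 3] == pytest.approx(1.0)
        assert np.all(np.diag(w.w) == 0)
        assert np.allclose(w.w, w.w.T)
        assert w.w[0, 1] == pytest.approx(1 / 3)

    def test_expanded_group_scale(self):
        levels = [1 + s / 3 for s in range(10)]  # 1, 4/3, ..., 4
        w = linear_weights(levels)
        assert w.w[0, 1] == pytest.approx((1 / 3) / 3)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            linear_weights([2, 2])


class TestKappa:
    def test_perfect_agreement(self):
        t = np.tile([[1.0], [3.0], [4.0], [2.0]], (1, 8))
        assert weighted_fleiss_kappa(t).kappa == pytest.approx(1.0)

    def test_single_category_table_defined_as_one(self):
        t = np.full((5, 4), 3.0)
        assert weighted_fleiss_kappa(t).kappa == 1.0

    def test_toy_tables_match_bruteforce_oracle(self, rng):
        w = linear_weights()
        for _ in range(25):
            t = rng.integers(1, 5, size=(3, 3)).astype(float)
            if len(np.unique(t)) == 1:
                continue
            ours = weighted_fleiss_kappa(t, w).kappa
            assert ours == pytest.approx(kappa_oracle(t, w), abs=1e-10)

    def test_independent_uniform_ratings_near_zero(self):
        rng = np.random.default_rng(7)
        t = rng.integers(1, 5, size=(500, 8)).astype(float)
        assert abs(weighted_fleiss_kappa(t).kappa) < 0.05

    def test_invariant_under_relabeling(self, rng):
        t = rng.integers(1, 5, size=(40, 6)).astype(float)
        k0 = weighted_fleiss_kappa(t).kappa
        perm_scans = rng.permutation(40)
        perm_raters = rng.permutation(6)
        k1 = weighted_fleiss_kappa(t[perm_scans][:, perm_raters]).kappa
        assert k0 == pytest.approx(k1, abs=1e-12)

    def test_scans_with_single_rating_dropped(self):
        t = np.array([[1.0, 1.0], [2.0, np.nan], [3.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="dropped"):
            res = weighted_fleiss_kappa(t)
        assert res.kappa == pytest.approx(1.0)

    def test_v_im_nonnegative(self, rng):
        for _ in range(10):
            t = rng.integers(1, 5, size=(30, 5)).astype(float)
            assert weighted_fleiss_kappa(t).v_im >= 0.0


class TestJackknife:
    def test_clone_raters_zero_variance(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 5, size=40).astype(float)
        t = np.tile(col[:, None], (1, 5))
        assert jackknife_rater_variance(t) == pytest.approx(0.0, abs=1e-18)

    def test_matches_hand_computation_on_four_raters(self, rng):
        t = rng.integers(1, 5, size=(25, 4)).astype(float)
        w = linear_weights()
        loo = np.array(
            [weighted_fleiss_kappa(np.delete(t, j, axis=1), w).kappa for j in range(4)]
        )
        manual = (4 - 1) / 4 * np.sum((loo - loo.mean()) ** 2)
        assert jackknife_rater_variance(t, w) == pytest.approx(manual, abs=1e-14)

    def test_needs_three_raters(self):
        with pytest.raises(ValueError):
            jackknife_rater_variance(np.full((5, 2), 3.0))


class TestIntraKappa:
    def test_self_consistent_raters(self):
        rng = np.random.default_rng(5)
        ratings = rng.integers(1, 5, size=(30, 8)).astype(float)
        t = table(ratings, repeats=ratings.copy())
        res = intra_kappa(t)
        assert res.kappa == pytest.approx(1.0)
        assert res.v_r == pytest.approx(0.0, abs=1e-18)

    def test_one_random_rater_dilutes_mean(self):
        rng = np.random.default_rng(11)
        n = 400
        ratings = rng.integers(1, 5, size=(n, 8)).astype(float)
        repeats = ratings.copy()
        repeats[:, 0] = rng.integers(1, 5, size=n)  # rater 0 re-rates at random
        res = intra_kappa(table(ratings, repeats))
        assert res.kappa == pytest.approx(7 / 8, abs=0.05)

    def test_v_r_is_unbiased_variance_over_eight(self):
        kappas = np.array([0.5, 0.5, 0.5, 0.5, 0.7, 0.7, 0.7, 0.7])
        expected = kappas.var(ddof=1) / 8
        # construct per-rater tables achieving exactly these kappas is
        # unnecessary: check the estimator arithmetic on the formula itself
        assert expected == pytest.approx(np.sum((kappas - 0.6) ** 2) / 7 / 8)


class TestGroupPairs:
    def test_count_for_eight_raters_groups_of_three(self):
        pairs, P = enumerate_group_pairs(8, 3)
        assert P == 560

    def test_count_for_four_raters_groups_of_one(self):
        pairs, P = enumerate_group_pairs(4, 1)
        assert P == 12
        # exhaustive listing: ordered pairs of distinct singletons
        listed = {(a, b) for (a,), (b,) in pairs}
        assert listed == {(a, b) for a in range(4) for b in range(4) if a != b}

    def test_groups_disjoint_and_sized(self):
        pairs, _ = enumerate_group_pairs(8, 3)
        for a, b in pairs:
            assert len(a) == len(b) == 3
            assert not set(a) & set(b)

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            enumerate_group_pairs(5, 3)


class TestGroup3:
    def test_clone_raters_perfect_agreement_and_zero_vr(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 5, size=30).astype(float)
        t = np.tile(col[:, None], (1, 8))
        res, extras = group3_kappa(t)
        assert res.kappa == pytest.approx(1.0)
        assert res.v_r == pytest.approx(0.0, abs=1e-18)  # all subset kappas equal
        assert extras["n_pairs"] == 560

    def test_miniature_six_raters_groups_of_two_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        t = rng.integers(1, 5, size=(20, 6)).astype(float)
        res, extras = group3_kappa(t, group_size=2)
        levels = sorted({s / 2 for s in range(2, 9)})
        w = linear_weights(levels)
        pairs, P = enumerate_group_pairs(6, 2)
        brute = []
        for a, b in pairs:
            ma = t[:, a].mean(axis=1)
            mb = t[:, b].mean(axis=1)
            brute.append(kappa_oracle(np.column_stack([ma, mb]), w))
        assert res.kappa == pytest.approx(np.mean(brute), abs=1e-10)

    def test_group_aggregation_beats_single_raters(self):
        # shared per-scan quality + independent rater noise
        rng = np.random.default_rng(17)
        n = 150
        quality = rng.integers(1, 5, size=n)
        noise = rng.integers(-1, 2, size=(n, 8))
        ratings = np.clip(quality[:, None] + noise, 1, 4).astype(float)
        inter = weighted_fleiss_kappa(ratings).kappa
        g3, _ = group3_kappa(ratings)
        assert g3.kappa > inter


class TestGainTests:
    def test_identical_tables_give_half_p(self):
        from emip.agreement import KappaResult

        a = KappaResult(kappa=0.6, v_im=0.0)
        with pytest.warns(RuntimeWarning):
            gain = kappa_gain(a, KappaResult(kappa=0.6, v_im=0.0), v_r_gain=0.0)
        assert gain.p_value == pytest.approx(0.5)

    def test_two_sigma_gain_p_value(self):
        from emip.agreement import KappaResult

        a = KappaResult(kappa=0.7, v_im=0.005)
        b = KappaResult(kappa=0.5, v_im=0.005)
        gain = kappa_gain(a, b, v_r_gain=0.0)
        # gain = 0.2 = 2 * sqrt(0.01)
        assert gain.p_value == pytest.approx(0.02275, abs=1e-4)

    def test_gain_variance_composition(self, rng):
        a = rng.integers(1, 5, size=(60, 8)).astype(float)
        b = np.clip(a + rng.integers(-1, 2, size=(60, 8)), 1, 4)
        v_r = inter_gain_rater_variance(a, b)
        assert v_r >= 0.0
        ra = weighted_fleiss_kappa(a)
        rb = weighted_fleiss_kappa(b)
        gain = kappa_gain(ra, rb, v_r)
        assert gain.variance == pytest.approx(v_r + ra.v_im + rb.v_im)

    def test_power_against_genuinely_more_concordant_ratings(self):
        rejections = 0
        n_rep = 40
        for i in range(n_rep):
            rng = np.random.default_rng(5000 + i)
            n = 120
            quality = rng.integers(1, 5, size=n)
            # eMIP raters track quality closely; MIP raters are noisier
            noisy = lambda sd: np.clip(
                quality[:, None] + rng.normal(0, sd, (n, 8)).round(), 1, 4
            ).astype(float)
            emip_t, mip_t = noisy(0.4), noisy(1.2)
            v_r = inter_gain_rater_variance(emip_t, mip_t)
            gain = kappa_gain(
                weighted_fleiss_kappa(emip_t), weighted_fleiss_kappa(mip_t), v_r
            )
            rejections += gain.p_value < 0.05
        assert rejections > n_rep // 2

    def test_two_sample_comparison(self):
        from emip.agreement import KappaResult

        res = kappa_compare(
            KappaResult(kappa=0.8, v_im=0.004), KappaResult(kappa=0.6, v_im=0.005)
        )
        from scipy import stats as sps

        assert res.p_value == pytest.approx(
            1 - sps.norm.cdf(0.2 / np.sqrt(0.009)), abs=1e-12
        )


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.2, "Poor agreement"),
            (0.1, "Slight agreement"),
            (0.3, "Fair agreement"),
            (0.5, "Moderate agreement"),
            (0.7, "Substantial agreement"),
            (0.95, "Almost perfect agreement"),
        ],
    )
    def test_bands(self, kappa, label):
        assert interpret_kappa(kappa) == label


class TestRatingTableIO:
    def _csv_df(self):
        rows = []
        for scan in range(4):
            for rater in range(3):
                for method in ("MIP", "eMIP"):
                    rows.append(
                        dict(
                            scan_id=f"s{scan}",
                            rater_id=f"r{rater}",
                            method=method,
                            session=1,
                            rating=3,
                        )
                    )
        return pd.DataFrame(rows)

    def test_round_trip_from_csv(self, tmp_path):
        df = self._csv_df()
        path = tmp_path / "ratings.csv"
        df.to_csv(path, index=False)
        t = RatingTable.from_csv(path, method="MIP")
        assert t.n_scans == 4 and t.n_raters == 3
        assert np.all(t.ratings == 3.0)

    def test_malformed_rating_rejected(self):
        df = self._csv_df()
        df.loc[0, "rating"] = 7
        with pytest.raises(ValueError, match="malformed"):
            RatingTable.from_csv(df, method="MIP")

    def test_missing_column_rejected(self):
        df = self._csv_df().drop(columns=["method"])
        with pytest.raises(ValueError, match="method"):
            RatingTable.from_csv(df, method="MIP")
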
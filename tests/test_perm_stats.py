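import itertools

import numpy as np
import pytest
import scipy.stats

from morphoconverge import perm_stats as pstats


def _design(n_per, q=1, rng=None, effects=None):
    """Six-cell lineage x period layout with optional added cell effects."""
    lin = np.repeat(["DE", "DE", "DL", "DL", "wild", "wild"], n_per)
    per = np.concatenate(
        [np.repeat(p, n) for p, n in zip(["historic", "modern"] * 3, n_per)]
    )
    y = rng.normal(size=(sum(n_per), q)) if rng is not None else np.zeros((sum(n_per), q))
    if effects:
        for (l_lev, p_lev), shift in effects.items():
            mask = (lin == l_lev) & (per == p_lev)
            y[mask] += shift
    return y, lin, per


class TestRrppAnova:
    def test_constant_response_rejected(self):
        y, lin, per = _design([4] * 6)
        with pytest.raises(pstats.DesignError, match="constant"):
            pstats.rrpp_anova(y, {"lineage": lin, "period": per}, n_perm=99, seed=0)

    def test_empty_cell_named(self, rng):
        lin = np.array(["DE"] * 8 + ["DL"] * 4, dtype=object)
        per = np.array(["historic", "modern"] * 4 + ["historic"] * 4, dtype=object)
        with pytest.raises(pstats.DesignError, match="lineage=DL.*period=modern|period=modern.*lineage=DL"):
            pstats.rrpp_anova(
                rng.normal(size=12),
                {"lineage": lin, "period": per},
                n_perm=99,
                seed=0,
            )

    def test_classical_one_way_f_exact(self, rng):
        y = rng.normal(size=40)
        groups = np.repeat(["a", "b"], 20)
        tab = pstats.rrpp_anova(
            y, {"g": groups}, model="g", n_perm=99, seed=1
        )
        f_ref = scipy.stats.f_oneway(y[:20], y[20:]).statistic
        assert tab.term("g")["F"] == pytest.approx(f_ref, abs=1e-10)

    def test_classical_three_group_f_exact(self, rng):
        y = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        tab = pstats.rrpp_anova(y, {"g": groups}, model="g", n_perm=99, seed=1)
        f_ref = scipy.stats.f_oneway(y[:10], y[10:20], y[20:]).statistic
        assert tab.term("g")["F"] == pytest.approx(f_ref, abs=1e-10)
        assert tab.term("g")["df"] == 2
        assert tab.term("residuals")["df"] == 27

    def test_exhaustive_permutation_p_matches_enumeration(self):
        # n=8, one factor with two balanced groups: RRPP under the
        # intercept-only reduced model is exactly raw-data permutation, so
        # the permutation p can be enumerated independently.
        rng = np.random.default_rng(42)
        y = rng.normal(size=8)
        groups = np.repeat(["a", "b"], 4)
        perms = np.array(list(itertools.permutations(range(8))))
        tab = pstats.rrpp_anova(
            y, {"g": groups}, model="g", n_perm=0, seed=None, permutations=perms
        )
        # oracle: closed-form one-way F for every permutation of y
        yp = y[perms]  # (40320, 8)
        ga, gb = yp[:, :4], yp[:, 4:]
        grand = yp.mean(axis=1)
        ss_between = 4 * (ga.mean(axis=1) - grand) ** 2 + 4 * (gb.mean(axis=1) - grand) ** 2
        ss_within = ((ga - ga.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (gb - gb.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        f_all = (ss_between / 1) / (ss_within / 6)
        f_obs = f_all[0]  # identity permutation is the first row
        p_oracle = np.mean(f_all >= f_obs - 1e-12 * max(1.0, abs(f_obs)))
        assert tab.term("g")["p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_exhaustive_two_by_two_matches_independent_rrpp_enumeration(self):
        # n=8, 2x2 design: enumerate all 8! permutations of each term's
        # reduced-model residuals and recompute F from scratch with lstsq.
        rng = np.random.default_rng(7)
        y = rng.normal(size=8)
        a = np.array(["u", "u", "u", "u", "v", "v", "v", "v"], dtype=object)
        b = np.array(["h", "h", "m", "m", "h", "h", "m", "m"], dtype=object)
        perms = np.array(list(itertools.permutations(range(8))))
        tab = pstats.rrpp_anova(
            y, {"a": a, "b": b}, model="a + b + a:b", permutations=perms
        )

        def hat(x):
            return x @ np.linalg.pinv(x)

        one = np.ones((8, 1))
        xa = np.column_stack([one, (a == "v").astype(float)])
        xb = np.column_stack([one, (b == "m").astype(float)])
        xab = np.column_stack([one, xa[:, 1], xb[:, 1]])
        xfull = np.column_stack([xab, xa[:, 1] * xb[:, 1]])
        h_full = hat(xfull)
        rss = lambda h, yy: float(yy @ (np.eye(8) - h) @ yy)
        for term, x_red, x_ft in (
            ("a", xb, xab),
            ("b", xa, xab),
            ("a:b", xab, xfull),
        ):
            h_red, h_ft = hat(x_red), hat(x_ft)
            fit_red = h_red @ y
            res_red = y - fit_red
            f_vals = np.empty(len(perms))
            for i, perm in enumerate(perms):
                yj = fit_red + res_red[list(perm)]
                ss_t = rss(h_red, yj) - rss(h_ft, yj)
                ss_r = rss(h_full, yj)
                f_vals[i] = (ss_t / 1) / (ss_r / 4)
            p_oracle = np.mean(f_vals >= f_vals[0] - 1e-12 * max(1.0, abs(f_vals[0])))
            assert tab.term(term)["p"] == pytest.approx(p_oracle, abs=1e-12)
            assert tab.term(term)["F"] == pytest.approx(f_vals[0], abs=1e-10)

    def test_type_two_equals_type_one_on_balanced_design(self, rng):
        y, lin, per = _design([6] * 6, q=3, rng=rng)
        tab = pstats.rrpp_anova(
            y, {"lineage": lin, "period": per}, n_perm=99, seed=0
        )
        # independent sequential (Type I) SS via nested least squares
        factors = {"lineage": lin, "period": per}
        seq = [("period",), ("lineage",), ("period", "lineage")]

        def rss(terms):
            x = pstats._design_matrix(factors, terms, len(y))
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(((y - x @ beta) ** 2).sum())

        prev = rss([])
        for i, term in enumerate(seq):
            cur = rss(seq[: i + 1])
            ss_type1 = prev - cur
            prev = cur
            assert tab.term(":".join(term))["SS"] == pytest.approx(ss_type1, abs=1e-9)

    def test_seed_reproducibility_bit_identical(self, rng):
        y, lin, per = _design([5] * 6, q=4, rng=rng)
        kwargs = dict(n_perm=199, seed=99)
        t1 = pstats.rrpp_anova(y, {"lineage": lin, "period": per}, **kwargs)
        t2 = pstats.rrpp_anova(y, {"lineage": lin, "period": per}, **kwargs)
        assert t1.table.equals(t2.table)

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(314)
        pvals = []
        for _ in range(500):
            y = rng.normal(size=36)
            groups = np.repeat(["a", "b", "c"], 12)
            tab = pstats.rrpp_anova(
                y, {"g": groups}, model="g", n_perm=199, seed=int(rng.integers(2**31))
            )
            pvals.append(tab.term("g")["p"])
        stat = scipy.stats.kstest(pvals, "uniform").statistic
        # critical value at alpha=0.01 for n=500
        assert stat < 1.628 / np.sqrt(500)

    def test_permutation_p_converges_to_classical(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        y[:15] += 0.8
        groups = np.repeat(["a", "b"], 15)
        tab = pstats.rrpp_anova(y, {"g": groups}, model="g", n_perm=4999, seed=0)
        f_obs = tab.term("g")["F"]
        p_classical = scipy.stats.f.sf(f_obs, 1, 28)
        assert tab.term("g")["p"] == pytest.approx(p_classical, abs=0.02)

    def test_r2_is_ss_over_total(self, rng):
        y, lin, per = _design([5] * 6, q=2, rng=rng)
        tab = pstats.rrpp_anova(y, {"lineage": lin, "period": per}, n_perm=99, seed=0)
        total = tab.term("total")["SS"]
        for term in ("lineage", "period", "period:lineage", "residuals"):
            assert tab.term(term)["R2"] == pytest.approx(
                tab.term(term)["SS"] / total, rel=1e-12
            )

    def test_min_p_is_one_over_nperm_plus_one(self, rng):
        # enormous effect: observed F tops every permutation
        y, lin, per = _design([6] * 6, q=1, rng=rng, effects={("wild", "historic"): 50.0, ("wild", "modern"): 50.0})
        tab = pstats.rrpp_anova(y, {"lineage": lin, "period": per}, n_perm=999, seed=0)
        assert tab.term("lineage")["p"] == pytest.approx(1 / 1000)


class TestPairwiseMeans:
    def test_duplicated_group_distance_zero(self, rng):
        y, lin, per = _design([5] * 6, q=3, rng=rng)
        # make modern DE rows an exact copy of historic DE rows
        mask_h = (lin == "DE") & (per == "historic")
        mask_m = (lin == "DE") & (per == "modern")
        y[mask_m] = y[mask_h]
        res = pstats.pairwise_means(y, lin, per, n_perm=99, seed=0)
        row = res.table[(res.table.group_a == "historic DE") & (res.table.group_b == "modern DE")]
        assert row["distance"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_distance_recovers_injected_shift(self):
        rng = np.random.default_rng(1)
        n = 400
        y, lin, per = _design([n] * 6, q=4, rng=rng, effects={("DE", "modern"): np.array([0.5, 0, 0, 0])})
        res = pstats.pairwise_means(y, lin, per, n_perm=99, seed=0)
        row = res.table[(res.table.group_a == "historic DE") & (res.table.group_b == "modern DE")]
        assert row["distance"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_distance_shrinks_with_n_under_equal_means(self):
        rng = np.random.default_rng(2)
        distances = {}
        for n in (20, 500):
            y, lin, per = _design([n] * 6, q=4, rng=rng)
            res = pstats.pairwise_means(y, lin, per, n_perm=99, seed=0)
            row = res.table[
                (res.table.group_a == "historic DL") & (res.table.group_b == "modern DL")
            ]
            distances[n] = row["distance"].iloc[0]
        assert distances[500] < distances[20]

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(100):
            y, lin, per = _design([10] * 6, q=5, rng=rng)
            res = pstats.pairwise_means(y, lin, per, n_perm=199, seed=rep)
            row = res.table[
                (res.table.group_a == "historic DE") & (res.table.group_b == "modern DE")
            ]
            pvals.append(row["p"].iloc[0])
        pvals = np.array(pvals)
        assert 0.3 < pvals.mean() < 0.7
        assert np.mean(pvals <= 0.05) <= 0.12

    def test_within_lineage_pairs_only_by_default(self, rng):
        y, lin, per = _design([4] * 6, q=2, rng=rng)
        res = pstats.pairwise_means(y, lin, per, n_perm=99, seed=0)
        assert len(res.table) == 3
        for _, row in res.table.iterrows():
            assert row.group_a.split()[-1] == row.group_b.split()[-1]

    def test_all_pairs_option(self, rng):
        y, lin, per = _design([4] * 6, q=2, rng=rng)
        res = pstats.pairwise_means(y, lin, per, n_perm=99, seed=0, pairs="all")
        assert len(res.table) == 15

    def test_small_group_rejected(self, rng):
        lin = np.array(["DE"] * 5 + ["DL"] * 4, dtype=object)
        per = np.array(["historic"] * 4 + ["modern"] + ["historic", "historic", "modern", "modern"], dtype=object)
        with pytest.raises(pstats.DesignError, match="< 2"):
            pstats.pairwise_means(rng.normal(size=9), lin, per, n_perm=99, seed=0)


class TestProcrustesVariance:
    def test_identical_members_zero(self):
        y = np.tile([1.0, 2.0, 3.0], (6, 1))
        pv = pstats.procrustes_variance(y, ["a"] * 3 + ["b"] * 3)
        assert pv["a"] == 0.0
        assert pv["b"] == 0.0

    def test_analytic_oracle(self):
        rng = np.random.default_rng(11)
        q, n_g, sigma = 6, 25, 0.7
        values = []
        for _ in range(200):
            y = rng.normal(scale=sigma, size=(n_g, q))
            values.append(pstats.procrustes_variance(y, ["g"] * n_g)["g"])
        values = np.array(values)
        expected = q * sigma**2 * (n_g - 1) / n_g
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - expected) < 3 * se

    def test_exchangeable_groups_equal_within_error(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(400, 4))
        groups = np.repeat(["a", "b"], 200)
        pv = pstats.procrustes_variance(y, groups)
        assert pv["a"] == pytest.approx(pv["b"], rel=0.15)



class TestPairwiseVariances:
    def test_identical_groups_statistic_zero(self, rng):
        y, lin, per = _design([5] * 6, q=3, rng=rng)
        mask_h = (lin == "DE") & (per == "historic")
        mask_m = (lin == "DE") & (per == "modern")
        y[mask_m] = y[mask_h] + 7.0  # same spread, shifted mean
        res = pstats.pairwise_variances(y, lin, per, n_perm=199, seed=0)
        row = res.table[(res.table.group_a == "historic DE") & (res.table.group_b == "modern DE")]
        assert row["distance"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert row["p"].iloc[0] > 0.5

    def test_group_variances_match_disparity(self, rng):
        y, lin, per = _design([6] * 6, q=4, rng=rng)
        res = pstats.pairwise_variances(y, lin, per, n_perm=99, seed=0)
        labels = np.array([f"{p} {g}" for g, p in zip(lin, per)], dtype=object)
        oracle = pstats.procrustes_variance(
            y - np.stack([y[labels == lab].mean(axis=0) for lab in labels]),
            labels,
        )
        for group, pv in res.group_variances.items():
            assert pv == pytest.approx(oracle[group], rel=1e-9)

    def test_power_at_sd_ratio_two(self):
        from morphoconverge.synthetic import DEFAULT_N_PER_CELL

        rng = np.random.default_rng(21)
        rejections = 0
        reps = 200
        for rep in range(reps):
            y, lin, per = _design(list(DEFAULT_N_PER_CELL), q=1, rng=rng)
            y[(lin == "DE") & (per == "historic")] *= 2.0
            res = pstats.pairwise_variances(y, lin, per, n_perm=199, seed=rep)
            row = res.table[
                (res.table.group_a == "historic DE") & (res.table.group_b == "modern DE")
            ]
            rejections += row["p"].iloc[0] <= 0.05
        assert rejections / reps >= 0.8

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(22)
        rejections = 0
        reps = 500
        for rep in range(reps):
            y, lin, per = _design([30] * 6, q=1, rng=rng)
            res = pstats.pairwise_variances(y, lin, per, n_perm=199, seed=rep)
            row = res.table[
                (res.table.group_a == "historic DE") & (res.table.group_b == "modern DE")
            ]
            rejections += row["p"].iloc[0] <= 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_seed_reproducibility(self, rng):
        y, lin, per = _design([5] * 6, q=2, rng=rng)
        r1 = pstats.pairwise_variances(y, lin, per, n_perm=199, seed=4)
        r2 = pstats.pairwise_variances(y, lin, per, n_perm=199, seed=4)
        assert r1.table.equals(r2.table)


def test_negative_z_allowed(rng):
    # observed below the null mean must yield a negative Z
    y, lin, per = _design([8] * 6, q=3, rng=rng)
    mask_h = (lin == "wild") & (per == "historic")
    mask_m = (lin == "wild") & (per == "modern")
    y[mask_m] = y[mask_h]  # raw distance exactly 0
    res = pstats.pairwise_means(y, lin, per, n_perm=199, seed=0)
    row = res.table[(res.table.group_a == "historic wild") & (res.table.group_b == "modern wild")]
    assert row["distance"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert row["Z"].iloc[0] < 0
    assert row["p"].iloc[0] > 0.5
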
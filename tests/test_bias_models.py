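import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from motionqc._utils import bh_fdr
from motionqc.io_formats import ThicknessDataset
from motionqc import bias_models as bm


def _predictors(rng, n):
    return pd.DataFrame({
        "age": rng.uniform(20, 89, n),
        "fd": rng.lognormal(-2, 0.5, n),
        "qc": np.array(["pass", "warn", "fail"])[rng.integers(0, 3, n)],
        "gender": np.array(["F", "M"])[rng.integers(0, 2, n)],
    })


def _sse(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


class TestAncova:
    def test_pure_age_effect_dominates(self, rng):
        n = 200
        pred = _predictors(rng, n)
        y = 5 - 0.02 * pred["age"] + 0.001 * rng.standard_normal(n)
        res = bm.ancova(y, pred)
        assert res.term("age")["partial_eta_sq"] > 0.99

    def test_terms_match_normal_equations_oracle(self, rng):
        # main-effects model: type III SS for a term is the SSE increase when
        # that term's columns are removed from the design
        n = 80
        pred = _predictors(rng, n)
        y = (2.5 - 0.005 * pred["age"].to_numpy()
             + 0.05 * rng.standard_normal(n))
        res = bm.ancova(y, pred)
        assert res.interaction_screen["refit_main_effects"]
        qc_d = pd.get_dummies(pred["qc"], drop_first=True).to_numpy(float)
        g_d = pd.get_dummies(pred["gender"], drop_first=True).to_numpy(float)
        blocks = {
            "age": pred["age"].to_numpy()[:, None],
            "fd": pred["fd"].to_numpy()[:, None],
            "C(qc, Sum)": qc_d,
            "C(gender, Sum)": g_d,
        }
        ones = np.ones((n, 1))
        X_full = np.hstack([ones] + list(blocks.values()))
        sse_full = _sse(X_full, y)
        df_resid = n - X_full.shape[1]
        for name, cols in blocks.items():
            rest = [v for k, v in blocks.items() if k != name]
            sse_red = _sse(np.hstack([ones] + rest), y)
            ss = sse_red - sse_full
            df = cols.shape[1]
            f = (ss / df) / (sse_full / df_resid)
            row = res.term(name)
            assert row["ss"] == pytest.approx(ss, rel=1e-8)
            assert row["F"] == pytest.approx(f, rel=1e-8)
            assert row["partial_eta_sq"] == pytest.approx(
                ss / (ss + sse_full), rel=1e-8
            )

    def test_balanced_design_type3_equals_type1(self, rng):
        # fully balanced 2x3 categorical design: orthogonality makes the
        # partial and sequential decompositions identical
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        qc = np.repeat(["pass", "warn", "fail"], 20)
        gender = np.tile(np.repeat(["F", "M"], 10), 3)
        y = rng.standard_normal(60)
        data = pd.DataFrame({"qc": qc, "gender": gender, "_y": y})
        fit = smf.ols("_y ~ C(qc, Sum) * C(gender, Sum)", data=data).fit()
        t3 = sm.stats.anova_lm(fit, typ=3).drop(index="Intercept")
        t1 = sm.stats.anova_lm(fit, typ=1)
        for term in ("C(qc, Sum)", "C(gender, Sum)"):
            assert t3.loc[term, "sum_sq"] == pytest.approx(t1.loc[term, "sum_sq"])

    def test_rank_deficient_design_names_alias(self, rng):
        n = 40
        pred = pd.DataFrame({
            "age": rng.uniform(20, 80, n),
            "fd": np.zeros(n),  # constant column aliases the intercept
        })
        pred["fd"] = pred["age"] * 2  # exact collinearity
        y = rng.standard_normal(n)
        with pytest.raises(ValueError, match="aliased"):
            bm.ancova(y, pred, screen_interactions=False)


class TestEffectSizeChange:
    def test_planted_fd_effect_detected(self, rng):
        n = 250
        pred = _predictors(rng, n)
        # outcome carries an age effect plus an FD effect collinear with age
        fd = 0.05 + 0.002 * pred["age"] + 0.02 * rng.standard_normal(n)
        pred["fd"] = fd
        y = 3 - 0.01 * pred["age"] - 2.0 * fd + 0.05 * rng.standard_normal(n)
        res = bm.effect_size_change(y, pred, n_perm=999, seed=2)
        assert res.delta > 0
        assert res.p_perm <= 0.01

    def test_independent_nuisance_gives_null_delta(self, rng):
        n = 200
        pred = _predictors(rng, n)
        y = 3 - 0.01 * pred["age"] + 0.1 * rng.standard_normal(n)
        res = bm.effect_size_change(y, pred, n_perm=199, seed=3)
        assert abs(res.delta) < 0.05
        assert res.p_perm > 0.05

    def test_pvalue_uniform_under_null(self, rng):
        # type-I calibration: rejection rate at alpha=0.05 within the exact
        # binomial 99% interval
        n, reps = 60, 400
        rejections = 0
        for i in range(reps):
            pred = _predictors(rng, n)
            y = 3 - 0.01 * pred["age"] + 0.1 * rng.standard_normal(n)
            res = bm.effect_size_change(y, pred, n_perm=99, seed=i)
            rejections += res.p_perm <= 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rejections <= hi

    def test_zero_permutations_rejected(self, rng):
        pred = _predictors(rng, 50)
        with pytest.raises(ValueError, match="n_perm"):
            bm.effect_size_change(rng.standard_normal(50), pred, n_perm=0)


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        y, x = rng.standard_normal(40), rng.standard_normal(40)
        res = bm.partial_correlation(y, x)
        r, p = stats.pearsonr(y, x)
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_exact_covariate_removal(self, rng):
        x = rng.standard_normal(30)
        c = rng.standard_normal(30)
        y = x + 3 * c
        assert bm.partial_correlation(y, x, c).r == pytest.approx(1.0)

    def test_matches_precision_matrix_oracle(self, rng):
        n = 60
        y = rng.standard_normal(n)
        x = 0.5 * y + rng.standard_normal(n)
        C = rng.standard_normal((n, 3)) + 0.3 * y[:, None]
        res = bm.partial_correlation(y, x, C)
        # oracle: negative scaled off-diagonal of the inverse covariance
        M = np.column_stack([y, x, C])
        P = np.linalg.inv(np.cov(M, rowvar=False))
        oracle = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_constant_residual_rejected(self, rng):
        c = rng.standard_normal(20)
        with pytest.raises(ValueError, match="constant"):
            bm.partial_correlation(2 * c, rng.standard_normal(20), c)


class TestVertexwise:
    def test_single_vertex_reduces_to_partial_correlation(self, rng):
        n = 50
        y = 2.5 + 0.1 * rng.standard_normal((n, 1))
        x = rng.standard_normal(n)
        C = rng.standard_normal((n, 2))
        m = bm.vertexwise_partial_corr(y, x, C)
        ref = bm.partial_correlation(y[:, 0], x, C)
        assert m.r[0] == pytest.approx(ref.r, abs=1e-12)
        assert m.p[0] == pytest.approx(ref.p, abs=1e-12)

    def test_planted_subset_detected(self, rng):
        n, v = 200, 150
        x = rng.standard_normal(n)
        T = 2.5 + 0.1 * rng.standard_normal((n, v))
        planted = np.arange(30)
        # effect size r ~ 0.4: slope * sd_x / sqrt(slope^2 + sd_e^2)
        slope = 0.4 / np.sqrt(1 - 0.4**2) * 0.1
        T[:, planted] += slope * x[:, None]
        m = bm.vertexwise_partial_corr(T, x)
        hit = m.q[planted] < 0.05
        false = m.q[30:] < 0.05
        assert hit.mean() > 0.9
        assert false.mean() < 0.1

    def test_null_map_rarely_significant(self, rng):
        n, v = 120, 200
        T = 2.5 + 0.1 * rng.standard_normal((n, v))
        m = bm.vertexwise_partial_corr(T, rng.standard_normal(n))
        assert (m.q < 0.05).mean() <= 0.05

    def test_constant_vertex_excluded(self, rng):
        T = 2.5 + 0.1 * np.abs(rng.standard_normal((30, 5)))
        T[:, 2] = 3.0
        m = bm.vertexwise_partial_corr(T, rng.standard_normal(30))
        assert np.isnan(m.r[2])
        assert m.n_undefined == 1


class TestBHFdr:
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_dominates_p(self, p):
        p = np.array(p)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()


class TestMatchedPools:
    def _cov(self, rng, n):
        return pd.DataFrame({
            "age": rng.uniform(20, 89, n),
            "gender": np.array(["F", "M"])[rng.integers(0, 2, n)],
        }, index=[f"p{i:03d}" for i in range(n)])

    def test_matches_brute_force(self, rng):
        cov = self._cov(rng, 120)
        flagged = set(cov.index[:8])
        pools = bm.matched_pools(flagged, cov, pool_size=10)
        retained = [p for p in cov.index if p not in flagged]
        for pid in flagged:
            cands = [c for c in retained
                     if cov.loc[c, "gender"] == cov.loc[pid, "gender"]]
            cands.sort(key=lambda c: (abs(cov.loc[c, "age"] - cov.loc[pid, "age"]), c))
            assert pools[pid] == cands[:10]

    def test_deterministic_tie_break(self):
        cov = pd.DataFrame({
            "age": [50, 49, 51, 48, 52],
            "gender": ["F"] * 5,
        }, index=["flag", "b", "a", "d", "c"])
        pools = bm.matched_pools({"flag"}, cov, pool_size=2)
        # |delta age| = 1 for a and b; lexicographic id breaks the tie
        assert pools["flag"] == ["a", "b"]

    def test_insufficient_candidates_named(self):
        cov = pd.DataFrame({
            "age": [50, 49, 48], "gender": ["F", "M", "M"],
        }, index=["flag", "x", "y"])
        with pytest.raises(ValueError, match="flag"):
            bm.matched_pools({"flag"}, cov, pool_size=2)


class TestMatchedBootstrap:
    def _setup(self, rng, n=100, shift=0.0):
        cov = pd.DataFrame({
            "age": rng.uniform(20, 89, n),
            "gender": np.array(["F", "M"])[rng.integers(0, 2, n)],
        }, index=[f"p{i:03d}" for i in range(n)])
        metric = pd.Series(2.5 + 0.1 * rng.standard_normal(n), index=cov.index)
        flagged = set(cov.index[:6])
        metric.loc[sorted(flagged)] += shift
        return flagged, metric, cov

    def test_degenerate_metric_p_one(self, rng):
        flagged, metric, cov = self._setup(rng)
        metric[:] = 2.5
        res = bm.matched_bootstrap_null(flagged, metric, cov, n_boot=200, seed=0)
        assert res.p == 1.0
        assert res.null_sd == 0.0

    def test_strong_planted_shift_minimal_p(self, rng):
        flagged, metric, cov = self._setup(rng, shift=-0.9)  # many pool SDs
        res = bm.matched_bootstrap_null(flagged, metric, cov, n_boot=999, seed=1)
        assert res.p == pytest.approx(1 / 1000)

    def test_null_mean_matches_pool_average(self, rng):
        flagged, metric, cov = self._setup(rng)
        pools = bm.matched_pools(flagged, cov, pool_size=10)
        res = bm.matched_bootstrap_null(
            flagged, metric, cov, n_boot=20_000, seed=2, pools=pools
        )
        expect = np.mean([
            np.mean([metric.loc[c] for c in pools[p]]) for p in sorted(flagged)
        ])
        assert res.null_mean == pytest.approx(expect, abs=0.003)

    def test_nboot_guards(self, rng):
        flagged, metric, cov = self._setup(rng)
        with pytest.raises(ValueError):
            bm.matched_bootstrap_null(flagged, metric, cov, n_boot=0)
        with pytest.warns(UserWarning, match="coarse"):
            bm.matched_bootstrap_null(flagged, metric, cov, n_boot=50, seed=0)

    def test_bit_reproducible(self, rng):
        flagged, metric, cov = self._setup(rng)
        a = bm.matched_bootstrap_null(flagged, metric, cov, n_boot=500, seed=9)
        b = bm.matched_bootstrap_null(flagged, metric, cov, n_boot=500, seed=9)
        assert a.p == b.p and a.null_mean == b.null_mean


class TestGroupTtest:
    def _ds(self, T):
        ids = [f"p{i}" for i in range(T.shape[0])]
        return ThicknessDataset(ids, T), ids

    def test_hand_computed_two_by_two(self):
        T = np.array([[2.0], [2.2], [2.6], [2.8]])
        ds, ids = self._ds(T)
        out = bm.vertexwise_group_ttest(ds, ids[:2], ids[2:])
        # pooled sd: s2 = 0.02, se = sqrt(0.02*(1/2+1/2)) -> t = -0.6/0.1414
        assert out.loc[0, "t"] == pytest.approx(-0.6 / np.sqrt(0.02), abs=1e-9)

    def test_null_proportion_small(self, rng):
        T = 2.5 + 0.1 * rng.standard_normal((60, 300))
        ds, ids = self._ds(T)
        out = bm.vertexwise_group_ttest(ds, ids[:30], ids[30:])
        assert (out["q"] < 0.05).mean() <= 0.05

    def test_planted_difference_detected(self, rng):
        # 0.3 mm difference, sd 0.2, n=30 per group
        T = 2.5 + 0.2 * rng.standard_normal((60, 100))
        T[:30, :20] -= 0.3
        ds, ids = self._ds(T)
        out = bm.vertexwise_group_ttest(ds, ids[:30], ids[30:])
        assert (out.loc[:19, "q"] < 0.05).mean() > 0.9

    def test_fdr_within_hemisphere(self, rng):
        T = 2.5 + 0.1 * rng.standard_normal((40, 10))
        ds, ids = self._ds(T)
        out = bm.vertexwise_group_ttest(ds, ids[:20], ids[20:])
        for h in ("L", "R"):
            mask = out["hemisphere"] == h
            np.testing.assert_allclose(
                out.loc[mask, "q"], bh_fdr(out.loc[mask, "p"].to_numpy())
            )


class TestEnvelope:
    def _cohort(self, rng, n=140, v=80, beta=0.0):
        ids = [f"p{i:03d}" for i in range(n)]
        cov = pd.DataFrame({
            "age": rng.uniform(20, 89, n),
            "gender": np.array(["F", "M"])[rng.integers(0, 2, n)],
        }, index=ids)
        fd = pd.Series(rng.lognormal(-2, 0.5, n), index=ids)
        T = 2.5 + 0.1 * rng.standard_normal((n, v))
        flagged = set(fd.sort_values().index[-10:])  # highest movers
        if beta:
            rows = [ids.index(p) for p in flagged]
            T[np.ix_(rows, np.arange(v // 2))] += beta
        ds = ThicknessDataset(ids, np.clip(T, 0.05, None))
        return ds, flagged, fd, cov

    def test_strong_bias_exits_envelope(self, rng):
        ds, flagged, fd, cov = self._cohort(rng, beta=-0.5)
        res = bm.leaveout_control_envelope(
            ds, flagged, fd, cov, n_groups=150, seed=4
        )
        assert res.exits_envelope
        assert res.frac_outside > 0.6

    def test_single_group_warns(self, rng):
        ds, flagged, fd, cov = self._cohort(rng)
        with pytest.warns(UserWarning, match="degenerate"):
            bm.leaveout_control_envelope(ds, flagged, fd, cov, n_groups=1, seed=0)

    def test_bias_separates_from_matched_null(self):
        # same cohort seed with and without the planted bias: the biased
        # after-flagging CDF departs from the control envelope far more
        outs = {}
        for beta in (0.0, -0.5):
            rng = np.random.default_rng(77)
            ds, flagged, fd, cov = self._cohort(rng, beta=beta)
            res = bm.leaveout_control_envelope(
                ds, flagged, fd, cov, n_groups=120, seed=5
            )
            outs[beta] = res.frac_outside
        assert outs[-0.5] > outs[0.0] + 0.2


class TestAgeEffectComparison:
    def _ds(self, rng, n=80, v=40):
        ids = [f"p{i:03d}" for i in range(n)]
        ages = pd.Series(rng.uniform(20, 89, n), index=ids)
        T = 2.5 - 0.006 * ages.to_numpy()[:, None] + 0.1 * rng.standard_normal((n, v))
        parcels = np.repeat(np.arange(8), v // 8)
        return ThicknessDataset(ids, np.clip(T, 0.05, None), parcels), ages, ids

    def test_identity_comparison_is_null(self, rng):
        ds, ages, ids = self._ds(rng)
        res = bm.age_effect_comparison(ds, ages, ids)
        assert res.z_diff == pytest.approx(0.0)
        assert res.ks["D"] == pytest.approx(0.0)
        assert res.bartlett["statistic"] == pytest.approx(0.0)
        assert (res.parcel_delta["delta_z"] == 0).all()

    def test_ks_matches_hand_enumeration(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        b = np.array([0.15, 0.25, 0.35, 0.9, 1.0])
        # independent stepwise oracle for the max CDF gap
        pts = np.union1d(a, b)
        gap = max(
            abs((a <= p).mean() - (b <= p).mean()) for p in pts
        )
        d = stats.ks_2samp(a, b).statistic
        assert d == pytest.approx(gap)

    def test_subset_requirement(self, rng):
        ds, ages, ids = self._ds(rng)
        with pytest.raises(ValueError, match="subset"):
            bm.age_effect_comparison(ds, ages, ids + ["ghost"])

    def test_attenuation_direction_with_bias(self, rng):
        # inject motion-like thinning in high-FD participants; removing them
        # moves the age correlation toward zero in bias-carrying parcels
        n, v = 200, 64
        ids = [f"p{i:03d}" for i in range(n)]
        ages = pd.Series(rng.uniform(20, 89, n), index=ids)
        T = 2.5 - 0.006 * ages.to_numpy()[:, None] + 0.25 * rng.standard_normal((n, v))
        old = ages.sort_values().index[-30:]
        rows = [ids.index(p) for p in old]
        # age-graded thinning bias in the first half of the parcels
        grade = ages.loc[old].to_numpy() - 40.0
        T[np.ix_(rows, np.arange(32))] -= 0.008 * grade[:, None]
        parcel_map = np.repeat(np.arange(8), 8)
        ds2 = ThicknessDataset(ids, np.clip(T, 0.05, None), parcel_map)
        retained = [p for p in ids if p not in set(old)]
        res = bm.age_effect_comparison(ds2, ages, retained)
        delta = res.parcel_delta.set_index("parcel")["delta_z"]
        biased, clean = delta.loc[:3], delta.loc[4:]
        assert (biased > 0).all()
        assert biased.mean() > clean.mean()
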
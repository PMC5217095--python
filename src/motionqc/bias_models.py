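"""Morphometric-bias statistics: ANCOVA, partial-correlation maps, matched
resampling nulls, and before/after-flagging age-effect comparison.

The battery asks, in order: does head motion (all-task mean FD) and the
visual QC rating predict gray-matter thickness independently of age and
gender (ANCOVA with type III sums of squares and partial eta-squared);
does controlling for the motion measures shrink the age effect more than
chance (effect-size-change permutation); where on the cortical surface
does motion relate to thickness (vertex-wise full-partial correlations
with Benjamini-Hochberg FDR); are flagged participants thinner than age-
and gender-matched controls (matched bootstrap null and vertex-wise
t-maps); and does removing flagged scans attenuate the apparent effect of
age (Bartlett / Fisher-z / Kolmogorov-Smirnov / parcel-wise contrasts).

Matched resampling draws, for every flagged participant, from the
``pool_size`` (default 10) retained participants of the same gender
closest in age, mirroring a demographically matched removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import linalg, stats

from ._utils import bh_fdr, perm_pvalue, substream
from .io_formats import ThicknessDataset


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass
class AncovaResult:
    terms: pd.DataFrame  # name, ss, df, F, p, partial_eta_sq
    model: dict  # adj_r_sq, df_model, df_resid, f, p
    interaction_screen: dict

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("name").loc[name]


@dataclass
class EffectSizeChange:
    eta_sq_without: float
    eta_sq_with: float
    delta: float
    p_perm: float
    n_perm: int
    seed: int


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int
    df: int


@dataclass
class PartialCorrMap:
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    covariates: list[str]
    n: int
    n_undefined: int


@dataclass
class BootstrapNull:
    observed: float
    null_mean: float
    null_sd: float
    null_quantiles: dict
    p: float
    tail: str
    n_boot: int
    pool_size: int
    seed: int


@dataclass
class EnvelopeResult:
    grid: np.ndarray
    cdf_lo: np.ndarray
    cdf_hi: np.ndarray
    cdf_after: np.ndarray
    cdf_before: np.ndarray
    exits_envelope: bool
    frac_outside: float
    n_groups: int
    seed: int


@dataclass
class AgeEffectComparison:
    r_before: float
    r_after: float
    z_diff: float
    p_z: float
    bartlett: dict
    ks: dict
    var_before: float
    var_after: float
    parcel_delta: pd.DataFrame
    vertex_r_before: np.ndarray
    vertex_r_after: np.ndarray


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # normalise column scales first so the rank test reflects collinearity,
    # not unit mismatches between raw and interaction columns
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        raise ValueError(
            f"rank-deficient design; aliased columns: "
            f"{[names[i] for i in np.where(norms == 0)[0]]}"
        )
    X = X / norms
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def ancova(
    outcome,
    predictors: pd.DataFrame,
    screen_interactions: bool = True,
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA of ``outcome`` on the supplied predictors.

    Categorical predictors (object/category dtype) enter with sum-to-zero
    contrasts.  The full-factorial model with all interactions is fitted
    first with type III sums of squares; if no interaction reaches
    ``alpha``, the model is refitted with main effects only and those
    terms are reported (type III equals type II in that model).  Partial
    eta-squared is SS_term / (SS_term + SS_resid).
    """
    data = predictors.copy()
    data = data.reset_index(drop=True)
    data["_y"] = np.asarray(outcome, float)
    if len(data) <= len(predictors.columns) + 1:
        raise ValueError("more model columns than observations")
    pieces = []
    for c in predictors.columns:
        if data[c].dtype == object or str(data[c].dtype) == "category":
            levels = data[c].dropna().unique()
            if len(levels) < 2:
                raise ValueError(f"categorical predictor {c!r} has a single level")
            pieces.append(f"C({c}, Sum)")
        else:
            pieces.append(c)

    def _fit(formula):
        fit = smf.ols(formula, data=data).fit()
        _check_full_rank(fit.model.exog, list(fit.model.exog_names))
        return fit

    try:
        full = _fit("_y ~ " + " * ".join(pieces))
    except ValueError as exc:
        if not screen_interactions or len(pieces) == 1:
            raise
        # the full-interaction model can be inestimable when a factor cell
        # is too small to support its per-cell slopes; report main effects
        fit = _fit("_y ~ " + " + ".join(pieces))
        table = sm.stats.anova_lm(fit, typ=3)
        screen = {"tested": False, "any_significant": False,
                  "refit_main_effects": True,
                  "note": f"full-interaction model not estimable ({exc})"}
        full = None
    if full is not None:
        table_full = sm.stats.anova_lm(full, typ=3)
        inter_rows = [ix for ix in table_full.index if ":" in ix]
        any_sig = bool((table_full.loc[inter_rows, "PR(>F)"] < alpha).any()) if inter_rows else False
        screen = {
            "tested": bool(screen_interactions and inter_rows),
            "any_significant": any_sig,
            "refit_main_effects": bool(screen_interactions and inter_rows and not any_sig),
        }
        if screen["refit_main_effects"]:
            fit = _fit("_y ~ " + " + ".join(pieces))
            table = sm.stats.anova_lm(fit, typ=3)
        else:
            fit, table = full, table_full
    table = table.drop(index=[ix for ix in ("Intercept",) if ix in table.index])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    rows = []
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        rows.append({
            "name": name,
            "ss": float(row["sum_sq"]),
            "df": int(row["df"]),
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
            "partial_eta_sq": float(row["sum_sq"] / (row["sum_sq"] + ss_resid)),
        })
    model = {
        "adj_r_sq": float(fit.rsquared_adj),
        "r_sq": float(fit.rsquared),
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
        "f": float(fit.fvalue),
        "p": float(fit.f_pvalue),
    }
    return AncovaResult(pd.DataFrame(rows), model, screen)


def _design(cols: list[np.ndarray], n: int) -> np.ndarray:
    return np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _dummies(values) -> list[np.ndarray]:
    d = pd.get_dummies(pd.Series(values).astype(str), drop_first=True)
    return [d[c].to_numpy(float) for c in d.columns]


def effect_size_change(
    outcome,
    predictors: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> EffectSizeChange:
    """Change in the age partial eta-squared after controlling motion/QC.

    ``predictors`` must contain age, gender, fd and qc.  The "without"
    model regresses the outcome on age and gender; the "with" model adds
    fd and qc.  The null permutes the (fd, qc) rows jointly against the
    fixed (age, gender, outcome) and recomputes the difference; the
    p-value is upper-tail with the plus-one rule.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(outcome, float)
    n = len(y)
    age = predictors["age"].to_numpy(float)
    gender = _dummies(predictors["gender"])
    fd = predictors["fd"].to_numpy(float)
    qc = _dummies(predictors["qc"])

    def eta_sq_age(nuisance_cols):
        X_full = _design(nuisance_cols + [age], n)
        X_red = _design(nuisance_cols, n)
        sse_full, sse_red = _sse(X_full, y), _sse(X_red, y)
        ss_age = sse_red - sse_full
        return ss_age / (ss_age + sse_full)

    eta_without = eta_sq_age(gender)
    eta_with = eta_sq_age(gender + [fd] + qc)
    delta = eta_without - eta_with

    rng = substream(seed, "effect_size_change")
    exceed = 0
    nuis = np.column_stack([fd] + qc) if qc else fd[:, None]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cols = [nuis[perm, j] for j in range(nuis.shape[1])]
        delta_p = eta_without - eta_sq_age(gender + cols)
        if delta_p >= delta:
            exceed += 1
    return EffectSizeChange(
        float(eta_without), float(eta_with), float(delta),
        perm_pvalue(exceed, n_perm), n_perm, seed,
    )


# ---------------------------------------------------------------------------
# partial correlations


def _residualize(a: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = a.shape[0]
    X = _design([] if covariates is None else [covariates[:, j] for j in range(covariates.shape[1])], n)
    beta, *_ = np.linalg.lstsq(X, a, rcond=None)
    return a - X @ beta


def partial_correlation(y, x, covariates=None) -> PartialCorrResult:
    """Full-partial Pearson correlation of y and x given shared covariates.

    Both variables are residualized on an intercept plus the covariates;
    the p-value uses a t distribution with n - k - 2 degrees of freedom
    (k covariates).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    C = None
    k = 0
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[1]:
            k = C.shape[1]
        else:
            C = None
    n = len(y)
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    ry = _residualize(y, C)
    rx = _residualize(x, C)
    if ry.std() <= 1e-10 * (np.abs(y).max() + 1e-300) or \
            rx.std() <= 1e-10 * (np.abs(x).max() + 1e-300):
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.corrcoef(ry, rx)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r, p, n, df)


def vertexwise_partial_corr(
    thickness: ThicknessDataset | np.ndarray,
    x,
    covariates=None,
    covariate_names: list[str] | None = None,
) -> PartialCorrMap:
    """Per-vertex full-partial correlation of thickness with x, with BH-FDR.

    Constant vertices yield undefined correlations; they are reported as
    NaN and excluded from the FDR adjustment.
    """
    T = thickness.thickness if isinstance(thickness, ThicknessDataset) else np.asarray(thickness, float)
    x = np.asarray(x, float)
    C = None
    k = 0
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
    n = T.shape[0]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rT = _residualize(T, C)
    rx = _residualize(x, C)
    sd_t = rT.std(axis=0)
    sd_x = rx.std()
    if sd_x == 0:
        raise ValueError("constant predictor residuals")
    defined = sd_t > 0
    r = np.full(T.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[defined] = (rT[:, defined] * rx[:, None]).mean(axis=0)[
            ...
        ] / (sd_t[defined] * sd_x)
    df = n - k - 2
    t = r * np.sqrt(df / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df)
    q = bh_fdr(p)
    names = covariate_names or [f"c{i}" for i in range(k)]
    return PartialCorrMap(r, p, q, names, n, int((~defined).sum()))


# ---------------------------------------------------------------------------
# matched resampling


def _matched_orders(
    flagged: set[str],
    covariates: pd.DataFrame,
    retained: set[str] | None,
    min_candidates: int,
) -> dict[str, list[str]]:
    """Full same-gender candidate lists sorted by (|age difference|, id)."""
    cov = covariates.copy()
    cov.index = cov.index.astype(str)
    flagged = {str(p) for p in flagged}
    if retained is None:
        retained = set(cov.index) - flagged
    retained = {str(p) for p in retained} - flagged
    orders = {}
    for pid in sorted(flagged):
        age, gender = cov.loc[pid, "age"], cov.loc[pid, "gender"]
        cands = cov.loc[sorted(retained)]
        cands = cands[cands["gender"] == gender]
        if len(cands) < min_candidates:
            raise ValueError(
                f"participant {pid!r}: only {len(cands)} same-gender retained "
                f"candidates, need {min_candidates}"
            )
        orders[pid] = sorted(
            cands.index, key=lambda c: (abs(cands.loc[c, "age"] - age), c)
        )
    return orders


def matched_pools(
    flagged: set[str],
    covariates: pd.DataFrame,
    retained: set[str] | None = None,
    pool_size: int = 10,
) -> dict[str, list[str]]:
    """Nearest-age same-gender retained candidates for each flagged member.

    ``covariates`` is indexed by participant_id with columns age and
    gender.  Ties in |age difference| break on the lexicographically
    smaller participant_id, so pools are deterministic.
    """
    orders = _matched_orders(flagged, covariates, retained, pool_size)
    return {pid: order[:pool_size] for pid, order in orders.items()}


def matched_bootstrap_null(
    flagged: set[str],
    metric: pd.Series,
    covariates: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    tail: str = "lower",
    pool_size: int = 10,
    pools: dict[str, list[str]] | None = None,
) -> BootstrapNull:
    """Null distribution of the flagged-group mean from matched controls.

    Each replicate draws (with replacement) one candidate per flagged
    member from that member's matched pool and records the group mean of
    ``metric``; the default lower-tail p-value asks how often a matched
    group is as low as the flagged group.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a very coarse null")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    metric = metric.copy()
    metric.index = metric.index.astype(str)
    flagged = {str(p) for p in flagged}
    if pools is None:
        pools = matched_pools(flagged, covariates, pool_size=pool_size)
    flagged_sorted = sorted(flagged)
    observed = float(metric.loc[flagged_sorted].mean())
    pool_vals = np.array(
        [[metric.loc[c] for c in pools[p]] for p in flagged_sorted], float
    )
    rng = substream(seed, "matched_bootstrap")
    draws = rng.integers(0, pool_vals.shape[1], size=(n_boot, len(flagged_sorted)))
    null = pool_vals[np.arange(len(flagged_sorted)), draws].mean(axis=1)
    if tail == "lower":
        p = perm_pvalue(int((null <= observed).sum()), n_boot)
    else:
        p = perm_pvalue(int((null >= observed).sum()), n_boot)
    qs = {q: float(np.quantile(null, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    return BootstrapNull(
        observed, float(null.mean()), float(null.std(ddof=1)), qs, p, tail,
        n_boot, pool_vals.shape[1], seed,
    )


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    v = np.sort(values[np.isfinite(values)])
    return np.searchsorted(v, grid, side="right") / len(v)


def leaveout_control_envelope(
    thickness: ThicknessDataset,
    flagged: set[str],
    fd: pd.Series,
    covariates: pd.DataFrame,
    n_groups: int = 1000,
    seed: int = 0,
    pool_size: int = 10,
    grid_size: int = 201,
) -> EnvelopeResult:
    """Envelope of thickness~FD correlation CDFs under matched removal.

    Each control group removes from the full sample one randomly chosen
    pool member per flagged participant (distinct members, so the control
    group has the same size as the retained sample) and recomputes the
    vertex-wise partial-correlation map.  The envelope is the pointwise
    2.5/97.5 percentile band of the empirical CDFs of those maps; the
    after-flagging CDF is flagged as significant when it exits the band.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups == 1:
        warnings.warn("n_groups=1 gives a degenerate envelope")
    fd = fd.copy()
    fd.index = fd.index.astype(str)
    flagged = {str(p) for p in flagged}
    all_ids = [str(p) for p in thickness.participants]
    retained = [p for p in all_ids if p not in flagged]
    # full sorted candidate orders: when overlapping pools collide during a
    # removal draw, the member falls through to its next-nearest available
    # same-gender candidate instead of deadlocking
    orders = _matched_orders(flagged, covariates, set(retained), pool_size)

    cov_num = covariates.copy()
    cov_num.index = cov_num.index.astype(str)
    gender_codes = pd.Categorical(cov_num["gender"]).codes

    def corr_map(ids):
        ds = thickness.subset(ids)
        rows = [all_ids.index(p) for p in ids]
        C = np.column_stack([
            cov_num.loc[ids, "age"].to_numpy(float),
            gender_codes[rows].astype(float),
        ])
        return vertexwise_partial_corr(ds, fd.loc[ids].to_numpy(), C).r

    r_before = corr_map(all_ids)
    r_after = corr_map(retained)
    finite = np.concatenate([r_before[np.isfinite(r_before)], r_after[np.isfinite(r_after)]])
    lo, hi = finite.min(), finite.max()
    pad = 0.05 * (hi - lo + 1e-9)
    grid = np.linspace(lo - pad, hi + pad, grid_size)

    rng = substream(seed, "leaveout_envelope")
    flagged_sorted = sorted(flagged)
    cdfs = np.empty((n_groups, grid_size))
    for g in range(n_groups):
        removed: set[str] = set()
        for pid in rng.permutation(flagged_sorted):
            options = [c for c in orders[pid] if c not in removed][:pool_size]
            if not options:
                raise ValueError(
                    f"candidates for {pid!r} exhausted while drawing a control group"
                )
            removed.add(options[rng.integers(len(options))])
        control = [p for p in all_ids if p not in removed]
        cdfs[g] = _ecdf_on_grid(corr_map(control), grid)
    cdf_lo = np.quantile(cdfs, 0.025, axis=0)
    cdf_hi = np.quantile(cdfs, 0.975, axis=0)
    cdf_after = _ecdf_on_grid(r_after, grid)
    cdf_before = _ecdf_on_grid(r_before, grid)
    outside = (cdf_after < cdf_lo - 1e-12) | (cdf_after > cdf_hi + 1e-12)
    return EnvelopeResult(
        grid, cdf_lo, cdf_hi, cdf_after, cdf_before,
        bool(outside.any()), float(outside.mean()), n_groups, seed,
    )


def vertexwise_group_ttest(
    thickness: ThicknessDataset,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per vertex with FDR applied within hemisphere.

    Pooled-variance t by default (Welch with ``equal_var=False``); the
    Benjamini-Hochberg adjustment runs separately within each hemisphere
    label.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 members")
    A = thickness.subset(group_a).thickness
    B = thickness.subset(group_b).thickness
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    q = np.full_like(p, np.nan)
    for h in np.unique(thickness.hemisphere):
        mask = thickness.hemisphere == h
        q[mask] = bh_fdr(p[mask])
    return pd.DataFrame({
        "vertex": np.arange(thickness.n_vertices),
        "hemisphere": thickness.hemisphere,
        "t": t,
        "p": p,
        "q": q,
    })


# ---------------------------------------------------------------------------
# age-effect comparison


def _columnwise_corr(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    denom = M.std(axis=0) * v.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Mc * vc[:, None]).mean(axis=0) / denom


def age_effect_comparison(
    thickness: ThicknessDataset,
    ages: pd.Series,
    after_ids: list[str],
    parcel_map: np.ndarray | None = None,
) -> AgeEffectComparison:
    """Compare age effects on thickness before vs after flag removal.

    Computes (i) Bartlett's test on the variances of participant mean
    thickness, (ii) a Fisher-z z-test on the two age~mean-thickness
    correlations (independent-samples SE, an approximation since the
    samples overlap), (iii) a two-sample Kolmogorov-Smirnov test on the
    vertex-wise age~thickness correlation vectors, and (iv) per-parcel
    differences in Fisher-z transformed correlations (after - before).
    """
    ages = ages.copy()
    ages.index = ages.index.astype(str)
    all_ids = [str(p) for p in thickness.participants]
    after_ids = [str(p) for p in after_ids]
    if not set(after_ids) <= set(all_ids):
        raise ValueError("after-set must be a subset of the before-set")
    parcels = parcel_map if parcel_map is not None else thickness.parcel_map

    T_before = thickness.thickness
    T_after = thickness.subset(after_ids).thickness
    age_b = ages.loc[all_ids].to_numpy(float)
    age_a = ages.loc[after_ids].to_numpy(float)

    mean_b, mean_a = T_before.mean(axis=1), T_after.mean(axis=1)
    if len(after_ids) == len(all_ids):
        bart = {"statistic": 0.0, "p": 1.0}
    else:
        s, p = stats.bartlett(mean_b, mean_a)
        bart = {"statistic": float(s), "p": float(p)}
    r_b = float(np.corrcoef(age_b, mean_b)[0, 1])
    r_a = float(np.corrcoef(age_a, mean_a)[0, 1])
    n1, n2 = len(all_ids), len(after_ids)
    se = np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z_diff = (np.arctanh(r_b) - np.arctanh(r_a)) / se
    p_z = float(2 * stats.norm.sf(abs(z_diff)))

    vr_b = _columnwise_corr(T_before, age_b)
    vr_a = _columnwise_corr(T_after, age_a)
    ok = np.isfinite(vr_b) & np.isfinite(vr_a)
    ks_stat, ks_p = stats.ks_2samp(vr_b[ok], vr_a[ok])
    ks = {"D": float(ks_stat), "p": float(ks_p)}

    rows = []
    if parcels is not None:
        for lab in np.unique(parcels):
            cols = parcels == lab
            pb = float(np.corrcoef(age_b, T_before[:, cols].mean(axis=1))[0, 1])
            pa = float(np.corrcoef(age_a, T_after[:, cols].mean(axis=1))[0, 1])
            rows.append({
                "parcel": int(lab),
                "r_before": pb,
                "r_after": pa,
                "z_before": float(np.arctanh(pb)),
                "z_after": float(np.arctanh(pa)),
                "delta_z": float(np.arctanh(pa) - np.arctanh(pb)),
            })
    return AgeEffectComparison(
        r_b, r_a, float(z_diff), p_z, bart, ks,
        float(np.var(mean_b, ddof=1)), float(np.var(mean_a, ddof=1)),
        pd.DataFrame(rows), vr_b, vr_a,
    )
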
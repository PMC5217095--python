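"""Cross-run motion stability, the combined flag rule, and overlap analysis.

Within-session stability is the matrix of Spearman rank correlations of
run-level mean FD across participants, with one-sided (positive
association) permutation p-values and Bonferroni correction over the
k(k-1)/2 run pairs.  The combined flag rule marks a participant when
either the all-task FD exceeds the mean + 1.5 SD threshold or the
composite visual rating is "fail".  The overlap analysis scores the
"fail" rating as a detector of FD-flagged high movers
(sensitivity/specificity) against a permutation null that redraws the
"fail" set at random from the cohort.

All permutation p-values use the plus-one rule (1 + exceedances) /
(1 + n_perm) and are therefore never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import perm_pvalue, substream
from .motion_metrics import HighMoverFlags


@dataclass
class CorrelationMatrix:
    runs: list[str]
    rho: np.ndarray  # k x k
    p_perm: np.ndarray  # k x k, NaN on the diagonal and undefined cells
    significant: np.ndarray  # Bonferroni-adjusted significance flags
    m: int  # number of pairwise comparisons
    n_perm: int
    seed: int
    method: str
    undefined_runs: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.runs, columns=self.runs)


@dataclass
class OverlapResult:
    sensitivity: float
    specificity: float
    p_sens: float
    p_spec: float
    counts: dict
    n_perm: int
    seed: int


@dataclass
class GroupTestResult:
    statistic_name: str  # H, U or F
    statistic: float
    z: float | None
    p: float
    p_adjusted: float | None
    eta_sq: float | None
    groups: tuple
    n: int
    df: tuple | None = None


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def stability_matrix(
    run_fdbar: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "spearman",
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Pairwise run-to-run correlation of mean FD across participants.

    ``run_fdbar`` is participants x runs (NaN for missing runs; pairs use
    pairwise-complete observations).  ``method`` is "spearman" (default)
    or "pearson".  The permutation test shuffles one run's values without
    replacement and counts null correlations >= the observed one.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    runs = list(run_fdbar.columns)
    k = len(runs)
    m = k * (k - 1) // 2
    rho = np.eye(k)
    p_perm = np.full((k, k), np.nan)
    undefined = []
    for j, r in enumerate(runs):
        col = run_fdbar[r].dropna()
        if col.nunique() <= 1:
            undefined.append(r)
    if undefined:
        warnings.warn(f"constant run column(s), correlations undefined: {undefined}")
    for i in range(k):
        for j in range(i + 1, k):
            pair = run_fdbar[[runs[i], runs[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < 3 or runs[i] in undefined or runs[j] in undefined:
                rho[i, j] = rho[j, i] = np.nan
                continue
            if method == "spearman":
                x, y = _rank(x), _rank(y)
            r_obs = float(np.corrcoef(x, y)[0, 1])
            rho[i, j] = rho[j, i] = r_obs
            rng = substream(seed, "stability", runs[i], runs[j])
            xc = (x - x.mean()) / x.std()
            yc = (y - y.mean()) / y.std()
            perm_idx = np.argsort(rng.random((n_perm, len(xc))), axis=1)
            null = (xc[perm_idx] @ yc) / len(xc)
            p = perm_pvalue(int((null >= r_obs).sum()), n_perm)
            p_perm[i, j] = p_perm[j, i] = p
    significant = p_perm * m < alpha
    return CorrelationMatrix(
        runs, rho, p_perm, significant, m, n_perm, seed, method, undefined
    )


def scan_order_test(run_table: pd.DataFrame, run_order: list[str] | None = None) -> GroupTestResult:
    """One-way ANOVA of run-level mean FD across scan positions.

    Observations are run x participant values; groups are runs (in
    acquisition order when given).
    """
    runs = run_order or list(pd.unique(run_table["run_id"]))
    groups = [
        run_table.loc[run_table["run_id"] == r, "fd_bar"].dropna().to_numpy()
        for r in runs
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 runs")
    if any(len(g) == 0 for g in groups):
        empty = [r for r, g in zip(runs, groups) if len(g) == 0]
        raise ValueError(f"empty run group(s): {empty}")
    f, p = stats.f_oneway(*groups)
    n_obs = sum(len(g) for g in groups)
    return GroupTestResult(
        "F", float(f), None, float(p), None, None, tuple(runs), n_obs,
        df=(len(groups) - 1, n_obs - len(groups)),
    )


def group_difference_tests(
    all_task: pd.Series,
    composite: pd.Series,
    bonferroni_m: int = 3,
) -> list[GroupTestResult]:
    """Kruskal-Wallis across rating groups plus pairwise rank-sum tests.

    Pairwise tests report the Mann-Whitney U of the first group, a
    tie-corrected normal-approximation z, Bonferroni-adjusted two-sided p,
    and the approximate rank eta-squared z^2 / n.
    """
    df = pd.DataFrame({"fd": all_task, "rating": composite}).dropna()
    levels = [lvl for lvl in ("pass", "warn", "fail") if (df["rating"] == lvl).any()]
    groups = {lvl: df.loc[df["rating"] == lvl, "fd"].to_numpy() for lvl in levels}
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty rating groups")
    h, p = stats.kruskal(*groups.values())
    results = [
        GroupTestResult("H", float(h), None, float(p), None, None, tuple(levels), len(df),
                        df=(len(levels) - 1,))
    ]
    for a, b in [("pass", "warn"), ("pass", "fail"), ("warn", "fail")]:
        if a not in groups or b not in groups:
            continue
        x, y = groups[a], groups[b]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"pairwise test {a} vs {b} skipped: group too small")
            continue
        u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
        n1, n2 = len(x), len(y)
        mu = n1 * n2 / 2
        # tie-corrected variance of U
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie = (counts**3 - counts).sum() / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12 * (n + 1 - tie))
        z = (u - mu) / sigma if sigma > 0 else 0.0
        p2 = float(2 * stats.norm.sf(abs(z)))
        results.append(
            GroupTestResult(
                "U", u, float(z), p2, min(1.0, p2 * bonferroni_m),
                float(z**2 / n), (a, b), n,
            )
        )
    return results


def combine_flags(high_movers: HighMoverFlags, composite: pd.Series) -> pd.DataFrame:
    """Combine the FD rule with "fail" ratings into per-participant flags.

    ``composite`` maps participant_id -> composite rating.  Returns a
    DataFrame with columns participant_id, flagged, source in
    {fd, qc, both, none}.
    """
    fd_ids = set(high_movers.flags)
    qc_ids = set(map(str, composite.index))
    if fd_ids != qc_ids:
        raise ValueError(
            "participant universes differ: "
            f"only-FD={sorted(fd_ids - qc_ids)[:5]}, only-QC={sorted(qc_ids - fd_ids)[:5]}"
        )
    rows = []
    for pid in sorted(fd_ids):
        fd = high_movers.flags[pid]
        qc = str(composite.loc[pid]).lower() == "fail"
        source = {(True, True): "both", (True, False): "fd",
                  (False, True): "qc", (False, False): "none"}[(fd, qc)]
        rows.append({"participant_id": pid, "flagged": fd or qc, "source": source})
    return pd.DataFrame(rows)


def overlap_analysis(
    fd_flags: set[str],
    qc_fails: set[str],
    universe: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Sensitivity/specificity of "fail" ratings for FD-flag detection.

    Sensitivity is the proportion of FD-flagged participants rated
    "fail"; specificity is the proportion of non-FD-flagged participants
    rated pass or warn.  The permutation null redraws the "fail" set
    (same size) uniformly without replacement from the cohort and scores
    both proportions, giving upper-tail p-values.
    """
    ids = sorted(universe)
    n_total = len(ids)
    if not fd_flags:
        raise ValueError("sensitivity undefined: empty FD-flag set")
    if not (fd_flags <= set(ids) and qc_fails <= set(ids)):
        raise ValueError("flag sets must be subsets of the universe")
    overlap = fd_flags & qc_fails
    sens = len(overlap) / len(fd_flags)
    spec = (n_total - len(fd_flags) - len(qc_fails - fd_flags)) / (n_total - len(fd_flags))

    rng = substream(seed, "overlap")
    is_fd = np.array([p in fd_flags for p in ids])
    n_fail = len(qc_fails)
    draws = np.argsort(rng.random((n_perm, n_total)), axis=1)[:, :n_fail]
    hit_fd = is_fd[draws].sum(axis=1)  # |random fail set ∩ fd_flags|
    null_sens = hit_fd / len(fd_flags)
    null_spec = (n_total - len(fd_flags) - (n_fail - hit_fd)) / (n_total - len(fd_flags))
    p_sens = perm_pvalue(int((null_sens >= sens).sum()), n_perm)
    p_spec = perm_pvalue(int((null_spec >= spec).sum()), n_perm)
    counts = {
        "n_total": n_total,
        "n_fd_flagged": len(fd_flags),
        "n_qc_fail": len(qc_fails),
        "n_overlap": len(overlap),
        "n_union": len(fd_flags | qc_fails),
    }
    return OverlapResult(sens, spec, p_sens, p_spec, counts, n_perm, seed)


def overlap_from_counts(n_total: int, n_fd: int, n_fail: int, n_union: int) -> dict:
    """Sensitivity/specificity implied by marginal and union counts alone.

    The overlap follows by inclusion-exclusion: |A∩B| = |A| + |B| - |A∪B|.
    """
    n_overlap = n_fd + n_fail - n_union
    if n_overlap < 0 or n_overlap > min(n_fd, n_fail):
        raise ValueError("inconsistent counts")
    sens = n_overlap / n_fd
    spec = (n_total - n_fd - (n_fail - n_overlap)) / (n_total - n_fd)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_overlap": n_overlap,
        "n_union": n_union,
    }
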
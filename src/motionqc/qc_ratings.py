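"""Composite visual QC ratings, inter-rater agreement and cohort contrasts.

T1-weighted scans are rated pass / warn / fail by each rater; the
composite rating is the most stringent (worst) of the contributing
ratings.  Agreement between two raters is quantified with unweighted
Cohen's kappa, with the asymptotic (Fleiss-Cohen-Everitt) standard error
for the confidence interval and a normal-approximation p-value from the
null-hypothesis standard error.  Rating distributions of two cohorts are
compared with a 2x3 Pearson contingency chi-square (df = 2, no continuity
correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import RATING_CODES, RATING_LEVELS, RatingRecord

_CODE_TO_LEVEL = {v: k for k, v in RATING_CODES.items()}


@dataclass
class CompositeRating:
    participant_id: str
    rating: str
    rater_ratings: dict[str, str]


@dataclass
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    dropped_columns: list[int]


def composite_rating(records: list[RatingRecord]) -> CompositeRating:
    """Worst-of-raters composite for one participant's records."""
    if not records:
        raise ValueError("need at least one rating record")
    pids = {r.participant_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records span multiple participants: {sorted(pids)}")
    worst = min(records, key=lambda r: RATING_CODES[r.rating])
    return CompositeRating(
        worst.participant_id,
        worst.rating,
        {r.rater_id: r.rating for r in records},
    )


def composite_table(records: list[RatingRecord]) -> pd.DataFrame:
    """Composite ratings for all participants; one row per participant."""
    by_pid: dict[str, list[RatingRecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    rows = []
    for pid, recs in by_pid.items():
        comp = composite_rating(recs)
        rows.append({"participant_id": pid, "composite": comp.rating, **comp.rater_ratings})
    return pd.DataFrame(rows)


def cohen_kappa(ratings1, ratings2, ci_level: float = 0.95) -> AgreementResult:
    """Unweighted Cohen's kappa for two equal-length rating vectors.

    CI uses the Fleiss-Cohen-Everitt asymptotic SE; the p-value is a
    two-sided normal approximation of kappa over its null SE.
    """
    r1 = [str(x).lower() for x in ratings1]
    r2 = [str(x).lower() for x in ratings2]
    if len(r1) != len(r2):
        raise ValueError("rating vectors must have equal length")
    n = len(r1)
    if n == 0:
        raise ValueError("empty rating vectors")
    bad = (set(r1) | set(r2)) - set(RATING_LEVELS)
    if bad:
        raise ValueError(f"unknown rating level(s) {sorted(bad)}")
    k = len(RATING_LEVELS)
    table = np.zeros((k, k))
    idx = {lvl: i for i, lvl in enumerate(RATING_LEVELS)}
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    p = table / n
    p_row, p_col = p.sum(axis=1), p.sum(axis=0)
    po = np.trace(p)
    pe = float(p_row @ p_col)
    if pe >= 1.0 - 1e-12:
        raise ValueError(
            "kappa undefined: both raters used a single category"
        )
    kappa = (po - pe) / (1 - pe)

    # Fleiss, Cohen & Everitt large-sample variance
    a_term = sum(
        p[i, i] * (1 - (p_row[i] + p_col[i]) * (1 - kappa)) ** 2 for i in range(k)
    )
    b_term = (1 - kappa) ** 2 * sum(
        p[i, j] * (p_col[i] + p_row[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    c_term = (kappa - pe * (1 - kappa)) ** 2
    var = (a_term + b_term - c_term) / (n * (1 - pe) ** 2)
    se = np.sqrt(max(var, 0.0))

    # null-hypothesis SE (kappa = 0)
    var0 = (pe + pe**2 - float(sum(p_row * p_col * (p_row + p_col)))) / (
        n * (1 - pe) ** 2
    )
    se0 = np.sqrt(max(var0, 1e-300))
    z = kappa / se0
    pval = float(2 * stats.norm.sf(abs(z)))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    return AgreementResult(
        float(kappa), float(kappa - zcrit * se), float(kappa + zcrit * se), pval, n
    )


def cohort_rating_chisq(counts_ref, counts_test) -> ChiSquareResult:
    """Pearson chi-square comparing two cohorts' pass/warn/fail counts."""
    obs = np.array([counts_ref, counts_test], dtype=float)
    if obs.shape != (2, 3):
        raise ValueError("expected two vectors of 3 counts (pass, warn, fail)")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("each cohort must have a positive total")
    dropped = list(np.where(obs.sum(axis=0) == 0)[0])
    if dropped:
        warnings.warn(
            f"rating column(s) {dropped} have zero total and were dropped; df reduced"
        )
        obs = obs[:, obs.sum(axis=0) > 0]
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), obs, expected, dropped)


def rating_distribution(composites) -> pd.DataFrame:
    """Counts and percentages (2 dp) of composite ratings per level."""
    s = pd.Series([str(c).lower() for c in composites])
    if s.empty:
        raise ValueError("need at least one composite rating")
    counts = s.value_counts().reindex(RATING_LEVELS, fill_value=0)
    pct = (100 * counts / counts.sum()).round(2)
    return pd.DataFrame({"count": counts, "percent": pct})
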
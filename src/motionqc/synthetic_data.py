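"""Synthetic lifespan cohorts with the statistical structure the analysis
assumes, plus ground truth for parameter-recovery tests.

The generator emulates a single-session adult lifespan protocol: ages
sampled with a minimum per decade, seven fMRI runs in four task
categories, a T1-weighted scan rated by two raters, and a vertex-wise
cortical thickness matrix.  Its moving parts:

* Motion propensity is log-normal.  The participant-level log mean is
  ``intercept + age_slope * age + N(0, between_run_sd)`` and each run's
  mean-FD target is ``exp`` of that plus within-run noise, which
  reproduces right-skewed, leptokurtic mean-FD distributions, a positive
  age-motion correlation, and high but imperfect cross-run rank
  stability.  The default slopes and variances are inverted analytically
  from two targets -- an age~all-task-FD Spearman correlation of 0.44 and
  a run-pair Spearman correlation of 0.80 -- via the Pearson/Spearman
  relation for bivariate normal ranks (r = 2 sin(pi * rho / 6)).
* Realignment series are six independent random walks whose increments
  are rescaled so the computed mean FD of each run equals its target
  exactly.
* The latent T1 artifact severity equals the fMRI log-propensity plus
  noise (the premise that people who move in one scan move in others,
  made explicit); each rater thresholds a noisy copy of the standardized
  severity at fixed marginal cutpoints, which yields ordinal pass / warn
  / fail ratings coupled to motion with moderate inter-rater agreement
  (default calibration: Cohen's kappa ~ 0.48).
* Thickness is a baseline minus age-related thinning per vertex, a small
  gender offset, plus a motion bias ``motion_beta * severity`` confined
  to a contiguous-parcel bias region (default 20% of vertices), plus
  i.i.d. residual noise.

Everything is drawn from a single integer seed and is fully
deterministic; written files are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import substream
from .io_formats import (
    CohortTable,
    RatingRecord,
    RealignmentSeries,
    ThicknessDataset,
    write_covariates,
    write_manifest,
    write_ratings,
    write_realignment,
    write_thickness,
)
from .motion_metrics import DEFAULT_RADIUS_MM, compute_fd

#: (task, run_id, n_frames) of the emulated seven-run session
DEFAULT_RUNS = (
    ("vv", "vv1", 202),
    ("vv", "vv2", 202),
    ("words", "words", 231),
    ("scenes", "scenes1", 171),
    ("scenes", "scenes2", 171),
    ("scenes", "scenes3", 171),
    ("rest", "rest", 154),
)


@dataclass
class MotionParams:
    intercept: float  # log mm
    age_slope: float  # log mm per year
    between_run_sd: float  # participant-level log sd
    within_run_sd: float  # run-level log sd


@dataclass
class RatingParams:
    latent_noise_sd: float = 0.25  # log-FD units linking propensity to artifact
    rater_noise_sd: float = 0.51  # per-rater noise on the standardized severity
    # cumulative marginal cutpoints (P(pass), P(pass or warn)) per rater
    rater_cutpoints: tuple = ((0.703, 0.970), (0.699, 0.940))


@dataclass
class ThicknessParams:
    n_vertices: int = 2000
    n_parcels: int = 148
    baseline_mean: float = 2.5  # mm
    age_slope: float = -0.006  # mm per year, mean across vertices
    age_slope_sd: float = 0.002  # per-vertex spread of the thinning slope
    gender_effect: float = 0.02  # mm offset for the second gender level
    motion_beta: float = -2.5  # mm per mm of artifact severity, bias region only
    participant_sd: float = 0.1  # mm, global per-participant thickness offset
    residual_sd: float = 0.1  # mm
    bias_fraction: float = 0.2  # fraction of vertices carrying the motion bias


@dataclass
class GeneratorConfig:
    n_participants: int = 266
    age_range: tuple = (20, 89)
    per_decade_min: int = 30
    female_fraction: float = 169 / 266
    runs: tuple = DEFAULT_RUNS
    target_age_rho: float = 0.44  # Spearman, age vs all-task mean FD
    target_run_rho: float = 0.80  # Spearman, run-pair mean FD
    log_fd_sd: float = 0.5  # total log-scale sd of a run's mean FD
    median_fd: float = 0.12  # mm, all-task mean FD at the mean age
    motion: MotionParams | None = None
    rating: RatingParams = field(default_factory=RatingParams)
    thickness: ThicknessParams = field(default_factory=ThicknessParams)
    radius: float = DEFAULT_RADIUS_MM
    seed: int = 0

    def __post_init__(self):
        n_dec = _n_decades(self.age_range)
        if n_dec * self.per_decade_min > self.n_participants:
            raise ValueError(
                f"per-decade minimum infeasible: {n_dec} decades x "
                f"{self.per_decade_min} > n = {self.n_participants}"
            )
        if self.motion is None:
            self.motion = motion_params_from_targets(
                self.target_age_rho, self.target_run_rho, self.log_fd_sd,
                self.median_fd, self.runs, self.age_range,
            )


@dataclass
class SyntheticCohort:
    cohort: CohortTable
    run_table: pd.DataFrame  # participant_id, task, run_id, fd_bar
    realignment: list[RealignmentSeries] | None
    ratings: list[RatingRecord]
    thickness: ThicknessDataset
    truth: dict


def _n_decades(age_range) -> int:
    lo, hi = age_range
    return int(np.ceil((hi + 1 - lo) / 10))


def _age_plan_moments(n: int, age_range, per_decade_min: int) -> tuple[float, float]:
    """Mean and sd of the age-sampling plan (decade minima + uniform rest)."""
    lo, hi = age_range
    n_dec = _n_decades(age_range)
    means, variances = [], []
    for d in range(n_dec):
        a, b = lo + 10 * d, min(lo + 10 * (d + 1), hi)
        means.append((a + b) / 2)
        variances.append((b - a) ** 2 / 12)
    m_dec = float(np.mean(means))
    v_dec = float(np.mean(variances) + np.var(means))
    m_unif = (lo + hi) / 2
    v_unif = (hi - lo) ** 2 / 12
    w = n_dec * per_decade_min / n
    mean = w * m_dec + (1 - w) * m_unif
    var = w * (v_dec + m_dec**2) + (1 - w) * (v_unif + m_unif**2) - mean**2
    return mean, float(np.sqrt(var))


def _spearman_to_pearson(rho: float) -> float:
    """Pearson correlation of a bivariate normal with given rank correlation."""
    return 2 * np.sin(np.pi * rho / 6)


def motion_params_from_targets(
    age_rho: float,
    run_rho: float,
    log_sd: float,
    median_fd: float,
    runs=DEFAULT_RUNS,
    age_range=(20, 89),
    n: int = 266,
    per_decade_min: int = 30,
) -> MotionParams:
    """Invert the log-normal motion model from its correlation targets.

    On the log scale a run's mean FD is c + b*age + u + e with
    u ~ N(0, sb^2), e ~ N(0, sw^2).  The run-pair Pearson correlation is
    (b^2 sa^2 + sb^2) / V and the age correlation of the all-task average
    is b*sa / sqrt(b^2 sa^2 + sb^2 + f*sw^2), where f reflects the
    run-then-task averaging of the manifest; both targets are converted
    from Spearman via r = 2 sin(pi rho / 6) before inverting.
    """
    mean_age, sd_age = _age_plan_moments(n, age_range, per_decade_min)
    tasks: dict[str, int] = {}
    for task, _run, _nf in runs:
        tasks[task] = tasks.get(task, 0) + 1
    n_tasks = len(tasks)
    f = sum(1 / m for m in tasks.values()) / n_tasks**2
    V = log_sd**2
    P = _spearman_to_pearson(run_rho) * V  # participant-level variance
    sw2 = V - P
    if sw2 < 0:
        raise ValueError("run_rho target exceeds what log_fd_sd allows")
    v_age = _spearman_to_pearson(age_rho) ** 2 * (P + f * sw2)
    if v_age > P:
        raise ValueError("age_rho target incompatible with run_rho target")
    b = np.sqrt(v_age) / sd_age
    return MotionParams(
        intercept=float(np.log(median_fd) - b * mean_age),
        age_slope=float(b),
        between_run_sd=float(np.sqrt(P - v_age)),
        within_run_sd=float(np.sqrt(sw2)),
    )


def _sample_ages(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_range
    n_dec = _n_decades(cfg.age_range)
    parts = [
        rng.uniform(lo + 10 * d, min(lo + 10 * (d + 1), hi), cfg.per_decade_min)
        for d in range(n_dec)
    ]
    rest = cfg.n_participants - n_dec * cfg.per_decade_min
    parts.append(rng.uniform(lo, hi, rest))
    ages = np.concatenate(parts)
    rng.shuffle(ages)
    return ages


def _bias_region(tp: ThicknessParams) -> tuple[np.ndarray, np.ndarray]:
    """Parcel map (contiguous vertex blocks) and the bias-region mask.

    The bias region is a contiguous block of parcels in each hemisphere
    covering ~``bias_fraction`` of vertices, echoing regionally patterned
    motion effects without claiming anatomical correspondence.
    """
    n_v, n_p = tp.n_vertices, tp.n_parcels
    parcel_map = np.minimum((np.arange(n_v) * n_p) // n_v, n_p - 1)
    half_p = n_p // 2
    per_hemi = max(1, int(round(tp.bias_fraction * half_p)))
    start = half_p // 4
    bias_parcels = np.concatenate([
        np.arange(start, start + per_hemi),
        np.arange(half_p + start, half_p + start + per_hemi),
    ])
    bias_parcels = bias_parcels[bias_parcels < n_p]
    mask = np.isin(parcel_map, bias_parcels)
    return parcel_map, mask


def _make_realignment(
    pid: str, run_id: str, n_frames: int, target_fdbar: float,
    radius: float, rng: np.random.Generator,
) -> RealignmentSeries:
    # random-walk parameters whose increments are rescaled so the computed
    # mean FD matches the run target exactly (FD is linear in the increments)
    inc = rng.standard_normal((n_frames - 1, 6))
    inc[:, 3:] /= radius  # rotation increments contribute equal arc length
    params = np.vstack([np.zeros(6), np.cumsum(inc, axis=0)])
    series = RealignmentSeries(pid, run_id, params[:, :3], params[:, 3:])
    fd = compute_fd(series, radius=radius)
    scale = target_fdbar / fd.fd.mean()
    return RealignmentSeries(pid, run_id, params[:, :3] * scale, params[:, 3:] * scale)


def generate_cohort(
    config: GeneratorConfig | None = None,
    make_realignment: bool = True,
) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a single seed.

    With ``make_realignment=False`` the per-frame realignment series are
    skipped and only the run-level mean-FD table is produced (the series
    are constructed to reproduce those values exactly, so downstream
    statistics are identical); useful for large calibration runs.
    """
    cfg = config or GeneratorConfig()
    rng = substream(cfg.seed, "generate_cohort")
    n = cfg.n_participants
    width = len(str(n))
    ids = [f"sub-{i + 1:0{width}d}" for i in range(n)]
    ages = _sample_ages(cfg, rng)
    female = rng.random(n) < cfg.female_fraction
    gender = np.where(female, "F", "M")

    mp = cfg.motion
    mu = mp.intercept + mp.age_slope * ages + mp.between_run_sd * rng.standard_normal(n)

    rows = []
    for task, run_id, n_frames in cfg.runs:
        log_fd = mu + mp.within_run_sd * rng.standard_normal(n)
        for pid, v in zip(ids, np.exp(log_fd)):
            rows.append((pid, task, run_id, float(v), n_frames))
    run_table = pd.DataFrame(
        rows, columns=["participant_id", "task", "run_id", "fd_bar", "n_frames"]
    ).sort_values(["participant_id", "run_id"], kind="stable").reset_index(drop=True)

    realignment = None
    if make_realignment:
        realignment = [
            _make_realignment(
                r.participant_id, r.run_id, int(r.n_frames), r.fd_bar,
                cfg.radius, substream(cfg.seed, "realign", r.participant_id, r.run_id),
            )
            for r in run_table.itertuples()
        ]

    # latent T1 artifact severity and two-rater ordinal ratings
    rp = cfg.rating
    log_sev = mu + rp.latent_noise_sd * rng.standard_normal(n)
    severity = np.exp(log_sev)
    z = (log_sev - log_sev.mean()) / log_sev.std()
    ratings: list[RatingRecord] = []
    sd_y = np.sqrt(1 + rp.rater_noise_sd**2)
    for ridx, cut in enumerate(rp.rater_cutpoints, start=1):
        y = z + rp.rater_noise_sd * rng.standard_normal(n)
        t1, t2 = stats.norm.ppf(cut[0]) * sd_y, stats.norm.ppf(cut[1]) * sd_y
        labels = np.where(y < t1, "pass", np.where(y < t2, "warn", "fail"))
        ratings += [
            RatingRecord(pid, f"rater{ridx}", lab) for pid, lab in zip(ids, labels)
        ]

    # thickness
    tp = cfg.thickness
    parcel_map, bias_mask = _bias_region(tp)
    slope_v = tp.age_slope + tp.age_slope_sd * rng.standard_normal(tp.n_vertices)
    gender_v = np.full(tp.n_vertices, tp.gender_effect)
    g = female.astype(float)
    offset = tp.participant_sd * rng.standard_normal(n)
    T = (
        tp.baseline_mean
        + np.outer(ages, slope_v)
        + np.outer(g, gender_v)
        + tp.motion_beta * np.outer(severity, bias_mask.astype(float))
        + offset[:, None]
        + tp.residual_sd * rng.standard_normal((n, tp.n_vertices))
    )
    T = np.clip(T, 0.05, None)  # thickness is physically positive
    thickness = ThicknessDataset(ids, T, parcel_map)

    participants = pd.DataFrame(
        {"participant_id": ids, "age": ages, "gender": gender}
    )
    manifest = run_table[["participant_id", "task", "run_id"]].copy()
    cohort = CohortTable(participants, manifest)

    truth = {
        "config": {
            "n_participants": n,
            "age_range": list(cfg.age_range),
            "per_decade_min": cfg.per_decade_min,
            "seed": cfg.seed,
            "motion": asdict(mp),
            "rating": {
                "latent_noise_sd": rp.latent_noise_sd,
                "rater_noise_sd": rp.rater_noise_sd,
                "rater_cutpoints": [list(c) for c in rp.rater_cutpoints],
            },
            "thickness": asdict(tp),
        },
        "propensity_log": dict(zip(ids, mu.tolist())),
        "severity": dict(zip(ids, severity.tolist())),
        "participant_offset": dict(zip(ids, offset.tolist())),
        "bias_vertices": np.where(bias_mask)[0].tolist(),
        "vertex_age_slope": slope_v.tolist(),
    }
    return SyntheticCohort(cohort, run_table, realignment, ratings, thickness, truth)


def truth_report(cohort: SyntheticCohort) -> dict:
    """Ground-truth parameters and latents for parameter-recovery tests."""
    return cohort.truth


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write every file the readers consume, plus truth.json.

    Returns a dict of the written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": out / "covariates.csv",
        "manifest": out / "manifest.csv",
        "ratings": out / "ratings.csv",
        "thickness": out / "thickness.tsv",
        "parcels": out / "parcels.txt",
        "truth": out / "truth.json",
        "realignment_dir": out / "realignment",
    }
    write_covariates(cohort.cohort, paths["covariates"])
    write_manifest(cohort.cohort.manifest, paths["manifest"])
    write_ratings(cohort.ratings, paths["ratings"])
    write_thickness(cohort.thickness, paths["thickness"], paths["parcels"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
    if cohort.realignment is not None:
        paths["realignment_dir"].mkdir(exist_ok=True)
        for s in cohort.realignment:
            write_realignment(
                s, paths["realignment_dir"] / f"rp_{s.participant_id}_{s.run_id}.txt"
            )
    return {k: str(v) for k, v in paths.items()}
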
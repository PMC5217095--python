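"""End-to-end orchestration: FD -> summaries -> ratings -> flags -> bias
statistics, from one config file, with logged seeds.

Stages run in a fixed order and each writes its report before the next
starts, so a failure halts the pipeline with the stage name while the
partial outputs remain on disk.  Thickness-dependent stages are skipped
with a notice when no thickness matrix is configured.  Every randomized
stage derives its own substream from the master seed and its stage name,
so adding a stage never perturbs the draws of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_models, io_formats, motion_metrics, qc_ratings, stability_flagging
from ._utils import substream

AGE_COHORTS = {"YA": (20, 34), "ME": (35, 49), "ML": (50, 64), "OA": (65, 89)}


@dataclass
class PipelineConfig:
    outdir: str
    covariates: str
    manifest: str | None = None
    realignment_dir: str | None = None
    realignment_pattern: str = "rp_{participant_id}_{run_id}.txt"
    dialect: str = "spm_order"
    ratings: str | None = None
    thickness: str | None = None
    parcels: str | None = None
    radius: float = motion_metrics.DEFAULT_RADIUS_MM
    summary_stat: str = "mean"
    k: float = 1.5
    n_perm: int = 10_000
    n_perm_effect_size: int = 1000
    n_boot: int = 10_000
    n_envelope_groups: int = 1000
    pool_size: int = 10
    fdr_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for name in ("covariates", "manifest", "realignment_dir", "ratings",
                     "thickness", "parcels"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_json_default, sort_keys=True))


def _gender_codes(cov: pd.DataFrame) -> np.ndarray:
    return pd.Categorical(cov["gender"]).codes.astype(float)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage of the analysis; returns the run manifest dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    state: dict = {}
    log_path = out / "run.log"
    from . import __version__

    log_lines = [
        f"motionqc {__version__} seed={cfg.seed} config_hash={manifest['config_hash']}"
    ]

    def stage(name, func, *, skip_reason=None):
        entry: dict = {}
        if skip_reason:
            entry["status"] = "skipped"
            entry["reason"] = skip_reason
            manifest["stages"][name] = entry
            log_lines.append(f"stage {name}: skipped ({skip_reason})")
            return
        t0 = time.perf_counter()
        try:
            outputs = func() or {}
        except Exception as exc:  # halt with stage name, keep partial outputs
            entry.update(status="failed", error=str(exc))
            manifest["stages"][name] = entry
            log_lines.append(f"stage {name}: FAILED ({exc})")
            log_path.write_text("\n".join(log_lines) + "\n")
            _write_json(out / "manifest.json", manifest)
            raise StageError(name, exc) from exc
        entry["status"] = "ok"
        manifest["stages"][name] = entry
        log_lines.append(f"stage {name}: ok in {time.perf_counter() - t0:.3f}s")
        for key, path in outputs.items():
            manifest["outputs"][key] = str(path)

    cohort = io_formats.read_covariates(cfg.covariates, cfg.manifest)
    cov = cohort.participants.set_index("participant_id")
    state["cohort"] = cohort

    # --- motion summaries ---------------------------------------------------
    def _motion():
        series = []
        for r in cohort.manifest.itertuples():
            fname = cfg.realignment_pattern.format(
                participant_id=r.participant_id, run_id=r.run_id
            )
            series.append(
                io_formats.read_realignment(
                    Path(cfg.realignment_dir) / fname, cfg.dialect,
                    participant_id=str(r.participant_id), run_id=str(r.run_id),
                )
            )
        fd_series = [motion_metrics.compute_fd(s, radius=cfg.radius) for s in series]
        run_table, summary = motion_metrics.motion_summary_table(
            fd_series, cohort.manifest, stat=cfg.summary_stat
        )
        state["run_table"], state["summary"] = run_table, summary
        path = out / "motion_summary.tsv"
        summary.to_csv(path, sep="\t")
        run_path = out / "motion_runs.tsv"
        run_table.to_csv(run_path, sep="\t", index=False)
        return {"motion_summary": path, "motion_runs": run_path}

    have_motion = cfg.realignment_dir is not None and cfg.manifest is not None
    stage("motion", _motion,
          skip_reason=None if have_motion else "no realignment_dir/manifest configured")
    if not have_motion:
        raise StageError("motion", ValueError("motion inputs are required"))

    # --- cross-run stability ------------------------------------------------
    def _stability():
        wide = state["run_table"].pivot(
            index="participant_id", columns="run_id", values="fd_bar"
        )
        run_order = list(pd.unique(state["run_table"]["run_id"]))
        cm = stability_flagging.stability_matrix(
            wide[run_order], n_perm=cfg.n_perm, seed=cfg.seed
        )
        cm.to_frame().to_csv(out / "stability_rho.tsv", sep="\t")
        _write_json(out / "stability.json", {
            "runs": cm.runs, "rho": cm.rho, "p_perm": cm.p_perm,
            "significant": cm.significant.tolist(), "m": cm.m,
            "n_perm": cm.n_perm, "seed": cm.seed, "method": cm.method,
        })
        order = stability_flagging.scan_order_test(state["run_table"], run_order)
        _write_json(out / "scan_order.json", order)
        return {"stability_rho": out / "stability_rho.tsv",
                "stability": out / "stability.json",
                "scan_order": out / "scan_order.json"}

    stage("stability", _stability)

    # --- ratings ------------------------------------------------------------
    have_ratings = cfg.ratings is not None

    def _ratings():
        records = io_formats.read_ratings(cfg.ratings)
        comp = qc_ratings.composite_table(records)
        comp.to_csv(out / "composite_ratings.tsv", sep="\t", index=False)
        state["composite"] = comp.set_index("participant_id")["composite"]
        report: dict = {
            "distribution": qc_ratings.rating_distribution(state["composite"])
            .reset_index(names="rating"),
        }
        raters = sorted({r.rater_id for r in records})
        if len(raters) == 2:
            by = {r: {} for r in raters}
            for rec in records:
                by[rec.rater_id][rec.participant_id] = rec.rating
            common = sorted(set(by[raters[0]]) & set(by[raters[1]]))
            agreement = qc_ratings.cohen_kappa(
                [by[raters[0]][p] for p in common], [by[raters[1]][p] for p in common]
            )
            report["kappa"] = agreement
        # cohort chi-squares vs the youngest cohort
        comp_ages = cov.loc[state["composite"].index, "age"]
        counts = {}
        for name, (lo, hi) in AGE_COHORTS.items():
            sel = state["composite"][(comp_ages >= lo) & (comp_ages <= hi)]
            counts[name] = [int((sel == lvl).sum()) for lvl in io_formats.RATING_LEVELS]
        chis = {}
        ref = counts["YA"]
        if sum(ref) > 0:
            for name in ("ME", "ML", "OA"):
                if sum(counts[name]) > 0:
                    res = qc_ratings.cohort_rating_chisq(ref, counts[name])
                    chis[name] = {"statistic": res.statistic, "df": res.df, "p": res.p,
                                  "observed": res.observed.tolist()}
        report["cohort_counts"] = counts
        report["cohort_chisq_vs_YA"] = chis
        _write_json(out / "ratings.json", report)
        return {"composite_ratings": out / "composite_ratings.tsv",
                "ratings": out / "ratings.json"}

    stage("ratings", _ratings,
          skip_reason=None if have_ratings else "no ratings table configured")

    # --- FD vs rating group differences ---------------------------------
    def _group_tests():
        results = stability_flagging.group_difference_tests(
            state["summary"]["all_task"], state["composite"]
        )
        _write_json(out / "group_tests.json", results)
        return {"group_tests": out / "group_tests.json"}

    stage("group_tests", _group_tests,
          skip_reason=None if have_ratings else "requires ratings")

    # --- combined flags -------------------------------------------------
    def _flags():
        hm = motion_metrics.flag_high_movers(state["summary"]["all_task"], k=cfg.k)
        state["high_movers"] = hm
        if have_ratings:
            flags = stability_flagging.combine_flags(hm, state["composite"])
        else:
            flags = pd.DataFrame({
                "participant_id": sorted(hm.flags),
                "flagged": [hm.flags[p] for p in sorted(hm.flags)],
                "source": ["fd" if hm.flags[p] else "none" for p in sorted(hm.flags)],
            })
        state["flags"] = flags
        meta = {"k": hm.k, "sample_mean": hm.sample_mean, "sample_sd": hm.sample_sd,
                "threshold": hm.threshold, "n_flagged": int(flags["flagged"].sum())}
        io_formats.write_flag_report(
            flags, out / "flags.tsv", out / "flags.json", meta
        )
        return {"flags": out / "flags.tsv", "flags_json": out / "flags.json"}

    stage("flags", _flags)

    # --- overlap analysis -----------------------------------------------
    def _overlap():
        fd_set = state["high_movers"].flagged_ids
        qc_set = {p for p, r in state["composite"].items() if r == "fail"}
        res = stability_flagging.overlap_analysis(
            fd_set, qc_set, set(state["summary"].index.astype(str)),
            n_perm=cfg.n_perm, seed=cfg.seed,
        )
        _write_json(out / "overlap.json", res)
        return {"overlap": out / "overlap.json"}

    stage("overlap", _overlap,
          skip_reason=None if have_ratings else "requires ratings")

    # --- thickness-dependent stages ----------------------------------------
    have_thickness = cfg.thickness is not None
    skip = None if (have_thickness and have_ratings) else \
        "requires thickness matrix and ratings"
    if have_thickness:
        thickness = io_formats.read_thickness(cfg.thickness, cfg.parcels, cohort=cohort)
        state["thickness"] = thickness

    def _predictors():
        ids = [str(p) for p in state["thickness"].participants]
        return ids, pd.DataFrame({
            "age": cov.loc[ids, "age"].to_numpy(float),
            "fd": state["summary"].loc[ids, "all_task"].to_numpy(float),
            "qc": state["composite"].loc[ids].astype(str).to_numpy(),
            "gender": cov.loc[ids, "gender"].astype(str).to_numpy(),
        })

    def _ancova():
        ids, pred = _predictors()
        mean_thick = state["thickness"].thickness.mean(axis=1)
        res = bias_models.ancova(mean_thick, pred)
        change = bias_models.effect_size_change(
            mean_thick, pred, n_perm=cfg.n_perm_effect_size, seed=cfg.seed
        )
        retained = [p for p in ids
                    if not state["flags"].set_index("participant_id").loc[p, "flagged"]]
        sub = state["thickness"].subset(retained)
        res_after = bias_models.ancova(
            sub.thickness.mean(axis=1),
            pred.set_index(pd.Index(ids)).loc[retained].reset_index(drop=True),
        )
        qc_code = pd.Series(pred["qc"]).map(io_formats.RATING_CODES).to_numpy(float)
        gender_num = pd.Categorical(pred["gender"]).codes.astype(float)
        pc_qc = bias_models.partial_correlation(
            mean_thick, qc_code,
            np.column_stack([pred["age"], gender_num, pred["fd"]]),
        )
        pc_fd = bias_models.partial_correlation(
            mean_thick, pred["fd"].to_numpy(),
            np.column_stack([pred["age"], gender_num, qc_code]),
        )
        _write_json(out / "ancova.json", {
            "full_sample": res, "retained_sample": res_after,
            "effect_size_change": change,
            "partial_r_qc": pc_qc, "partial_r_fd": pc_fd,
        })
        state["retained"] = retained
        return {"ancova": out / "ancova.json"}

    stage("ancova", _ancova, skip_reason=skip)

    def _vertex_maps():
        ids, pred = _predictors()
        gender_num = pd.Categorical(pred["gender"]).codes.astype(float)
        C = np.column_stack([pred["age"], gender_num])
        fd = pred["fd"].to_numpy()
        before = bias_models.vertexwise_partial_corr(
            state["thickness"], fd, C, ["age", "gender"]
        )
        idx = {p: i for i, p in enumerate(ids)}
        rows = [idx[p] for p in state["retained"]]
        after = bias_models.vertexwise_partial_corr(
            state["thickness"].subset(state["retained"]), fd[rows], C[rows],
            ["age", "gender"],
        )
        for tag, m in (("before", before), ("after", after)):
            pd.DataFrame({"vertex": np.arange(len(m.r)), "r": m.r,
                          "p": m.p, "q": m.q}).to_csv(
                out / f"fd_thickness_map_{tag}.tsv", sep="\t", index=False)
        state["fd_map_before"], state["fd_map_after"] = before, after
        return {"fd_thickness_map_before": out / "fd_thickness_map_before.tsv",
                "fd_thickness_map_after": out / "fd_thickness_map_after.tsv"}

    stage("vertex_maps", _vertex_maps, skip_reason=skip)

    def _envelope():
        ids, pred = _predictors()
        flagged = set(state["flags"].loc[state["flags"]["flagged"], "participant_id"])
        env = bias_models.leaveout_control_envelope(
            state["thickness"], flagged,
            pd.Series(pred["fd"].to_numpy(), index=ids),
            cov.loc[ids, ["age", "gender"]],
            n_groups=cfg.n_envelope_groups, seed=cfg.seed, pool_size=cfg.pool_size,
        )
        _write_json(out / "envelope.json", env)
        return {"envelope": out / "envelope.json"}

    stage("envelope", _envelope, skip_reason=skip)

    def _matched_bootstrap():
        ids, _ = _predictors()
        flagged = set(state["flags"].loc[state["flags"]["flagged"], "participant_id"])
        mean_thick = pd.Series(state["thickness"].thickness.mean(axis=1), index=ids)
        pools = bias_models.matched_pools(
            flagged, cov.loc[ids, ["age", "gender"]], pool_size=cfg.pool_size
        )
        null = bias_models.matched_bootstrap_null(
            flagged, mean_thick, cov.loc[ids, ["age", "gender"]],
            n_boot=cfg.n_boot, seed=cfg.seed, pools=pools,
        )
        _write_json(out / "matched_bootstrap.json", null)
        # one matched control sample for the vertex-wise group comparison
        rng = substream(cfg.seed, "control_sample")
        orders = bias_models._matched_orders(
            flagged, cov.loc[ids, ["age", "gender"]], None, cfg.pool_size
        )
        control = []
        taken: set[str] = set()
        for pid in sorted(flagged):
            options = [c for c in orders[pid] if c not in taken][:cfg.pool_size]
            pick = options[rng.integers(len(options))]
            taken.add(pick)
            control.append(pick)
        tmap = bias_models.vertexwise_group_ttest(
            state["thickness"], sorted(flagged), control
        )
        tmap.to_csv(out / "flagged_vs_control_tmap.tsv", sep="\t", index=False)
        return {"matched_bootstrap": out / "matched_bootstrap.json",
                "flagged_vs_control_tmap": out / "flagged_vs_control_tmap.tsv"}

    stage("matched_bootstrap", _matched_bootstrap, skip_reason=skip)

    def _age_effects():
        ids, _ = _predictors()
        res = bias_models.age_effect_comparison(
            state["thickness"], cov.loc[ids, "age"], state["retained"]
        )
        res.parcel_delta.to_csv(out / "parcel_age_effects.tsv", sep="\t", index=False)
        _write_json(out / "age_effects.json", {
            "r_before": res.r_before, "r_after": res.r_after,
            "z_diff": res.z_diff, "p_z": res.p_z,
            "var_before": res.var_before, "var_after": res.var_after,
            "bartlett": res.bartlett, "ks": res.ks,
        })
        return {"age_effects": out / "age_effects.json",
                "parcel_age_effects": out / "parcel_age_effects.tsv"}

    stage("age_effects", _age_effects, skip_reason=skip)

    log_path.write_text("\n".join(log_lines) + "\n")
    _write_json(out / "manifest.json", manifest)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
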
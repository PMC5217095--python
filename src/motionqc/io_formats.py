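"""Readers and writers for every external table the pipeline touches.

Realignment-parameter files are plain text with six numeric columns per
frame.  Two column-order dialects occur in the wild and are handled
explicitly:

* ``spm_order`` -- tx ty tz rx ry rz (translations mm, rotations radians),
  the layout of SPM ``rp_*.txt`` files;
* ``mcflirt_order`` -- rx ry rz tx ty tz, the layout of MCFLIRT ``*.par``
  files.

Ratings, covariates and run manifests are delimited tables with a header
row; the thickness matrix is delimited text with one participant per row.
Participant and run identity always comes from explicit columns or a
manifest, never from filename parsing (a pattern helper is provided but is
never applied implicitly).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DIALECTS = ("spm_order", "mcflirt_order")
RATING_LEVELS = ("pass", "warn", "fail")  # ordinal, pass > warn > fail
RATING_CODES = {"pass": 2, "warn": 1, "fail": 0}


class FormatError(ValueError):
    """Raised when an input file violates its documented layout."""


@dataclass
class RealignmentSeries:
    """Per-frame rigid-body realignment estimates for one fMRI run."""

    participant_id: str
    run_id: str
    translations: np.ndarray  # (n_frames, 3) mm
    rotations: np.ndarray  # (n_frames, 3) radians
    dialect: str = "spm_order"

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n_frames, 3)")
        if self.translations.shape[0] < 1:
            raise ValueError("a realignment series needs at least one frame")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("realignment parameters must be finite")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class CohortTable:
    """Participant covariates plus the per-participant run manifest.

    ``participants`` has columns participant_id, age, gender and optionally
    icv; ``manifest`` has columns participant_id, task, run_id.
    """

    participants: pd.DataFrame
    manifest: pd.DataFrame | None = None

    def __post_init__(self):
        df = self.participants
        required = {"participant_id", "age", "gender"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"covariate table missing columns: {sorted(missing)}")
        if df["participant_id"].duplicated().any():
            dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
            raise FormatError(f"duplicate participant IDs: {dups}")
        if (df["age"] <= 0).any() or df["age"].isna().any():
            raise FormatError("age must be positive and non-missing")
        if df["gender"].isna().any():
            raise FormatError("gender must be non-missing")
        if df["gender"].nunique() > 2:
            raise FormatError("gender must be a 2-level categorical")

    @property
    def ids(self) -> list[str]:
        return self.participants["participant_id"].tolist()


@dataclass
class ThicknessDataset:
    """Participants x vertices cortical thickness (mm) with optional labels."""

    participants: list[str]
    thickness: np.ndarray  # (n_participants, n_vertices) mm
    parcel_map: np.ndarray | None = None  # per-vertex integer parcel label
    hemisphere: np.ndarray | None = None  # per-vertex 'L'/'R'

    def __post_init__(self):
        self.thickness = np.asarray(self.thickness, float)
        if self.thickness.ndim != 2 or self.thickness.shape[0] != len(self.participants):
            raise ValueError("thickness must be (n_participants, n_vertices)")
        bad = ~(np.isfinite(self.thickness) & (self.thickness > 0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"non-positive or non-finite thickness at row {r} (participant "
                f"{self.participants[r]!r}), vertex column {c}"
            )
        n_v = self.thickness.shape[1]
        if self.parcel_map is not None:
            self.parcel_map = np.asarray(self.parcel_map, int)
            if self.parcel_map.shape != (n_v,):
                raise FormatError(
                    f"parcel map has {self.parcel_map.size} labels for {n_v} vertices"
                )
        if self.hemisphere is None:
            # default convention: first half left hemisphere, second half right
            self.hemisphere = np.array(["L"] * (n_v // 2) + ["R"] * (n_v - n_v // 2))
        else:
            self.hemisphere = np.asarray(self.hemisphere)
            if self.hemisphere.shape != (n_v,):
                raise FormatError("hemisphere labels must match vertex count")

    @property
    def n_vertices(self) -> int:
        return self.thickness.shape[1]

    def subset(self, ids: Sequence[str]) -> "ThicknessDataset":
        index = {p: i for i, p in enumerate(self.participants)}
        missing = [p for p in ids if p not in index]
        if missing:
            raise KeyError(f"participants absent from thickness dataset: {missing}")
        rows = [index[p] for p in ids]
        return ThicknessDataset(
            list(ids), self.thickness[rows], self.parcel_map, self.hemisphere
        )


@dataclass
class RatingRecord:
    participant_id: str
    rater_id: str
    rating: str

    def __post_init__(self):
        if self.rating not in RATING_LEVELS:
            raise FormatError(
                f"unknown rating {self.rating!r}; allowed levels: {RATING_LEVELS}"
            )


# ---------------------------------------------------------------------------
# realignment parameter files


def _detect_delimiter(lines: list[str]) -> str:
    has_comma = [("," in ln) for ln in lines]
    has_tab = [("\t" in ln) for ln in lines]
    if any(has_comma):
        if not all(has_comma):
            raise FormatError("mixed delimiters: comma appears in only some lines")
        return ","
    if any(has_tab):
        if not all(has_tab):
            raise FormatError("mixed delimiters: tab appears in only some lines")
        return "\t"
    return ""  # generic whitespace


def read_realignment(
    path,
    dialect: str = "spm_order",
    participant_id: str = "",
    run_id: str = "",
    drop_initial_frames: int = 0,
) -> RealignmentSeries:
    """Read a 6-column realignment parameter file.

    ``drop_initial_frames`` discards the first k frames after parsing
    (dummy-frame handling); it is off by default because upstream tools
    usually emit parameters for retained frames only.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty realignment file")
    sep = _detect_delimiter(lines)
    rows = []
    for i, ln in enumerate(lines, start=1):
        parts = ln.split(sep) if sep else ln.split()
        parts = [p for p in parts if p.strip()]
        if len(parts) != 6:
            raise FormatError(
                f"{path}: line {i} has {len(parts)} columns, expected 6"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-numeric value ({exc})") from None
    arr = np.array(rows, float)[int(drop_initial_frames):]
    if arr.shape[0] < 1:
        raise FormatError(f"{path}: no frames left after dropping initial frames")
    if dialect == "spm_order":
        trans, rot = arr[:, :3], arr[:, 3:]
    else:  # mcflirt_order
        rot, trans = arr[:, :3], arr[:, 3:]
    return RealignmentSeries(participant_id, run_id, trans, rot, dialect)


def write_realignment(series: RealignmentSeries, path, dialect: str | None = None) -> None:
    dialect = dialect or series.dialect
    if dialect == "spm_order":
        arr = np.hstack([series.translations, series.rotations])
    elif dialect == "mcflirt_order":
        arr = np.hstack([series.rotations, series.translations])
    else:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    np.savetxt(path, arr, fmt="%.17e")


def parse_run_filename(name: str, pattern: str) -> dict:
    """Extract participant/run fields from a filename via a regex pattern.

    The pattern must use named groups, e.g. ``rp_(?P<participant_id>\\w+)_
    (?P<run_id>\\w+).txt``.  This helper is provided for convenience only;
    no reader ever applies it implicitly.
    """
    m = re.search(pattern, name)
    if m is None:
        raise FormatError(f"filename {name!r} does not match pattern {pattern!r}")
    return m.groupdict()


# ---------------------------------------------------------------------------
# ratings


def read_ratings(path) -> list[RatingRecord]:
    """Read a ratings table (participant_id, rater_id, rating) from CSV/TSV."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"participant_id", "rater_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["rating"] = df["rating"].str.strip().str.lower()
    bad = ~df["rating"].isin(RATING_LEVELS)
    if bad.any():
        raise FormatError(
            f"{path}: unknown rating value(s) {sorted(df.loc[bad, 'rating'].unique())}; "
            f"allowed levels: {RATING_LEVELS}"
        )
    dup = df.duplicated(subset=["participant_id", "rater_id"])
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "rater_id"]].values.tolist()
        raise FormatError(f"{path}: duplicate (participant, rater) records: {pairs}")
    return [
        RatingRecord(r.participant_id, r.rater_id, r.rating) for r in df.itertuples()
    ]


def write_ratings(records: Sequence[RatingRecord], path) -> None:
    pd.DataFrame(
        [(r.participant_id, r.rater_id, r.rating) for r in records],
        columns=["participant_id", "rater_id", "rating"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariates / manifest


def read_covariates(path, manifest_path=None) -> CohortTable:
    df = pd.read_csv(path, sep=None, engine="python")
    df["participant_id"] = df["participant_id"].astype(str)
    manifest = None
    if manifest_path is not None:
        manifest = read_manifest(manifest_path)
    return CohortTable(df, manifest)


def write_covariates(cohort: CohortTable, path) -> None:
    cohort.participants.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"participant_id", "task", "run_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# thickness


def read_thickness(
    path_matrix,
    path_parcels=None,
    path_hemisphere=None,
    cohort: CohortTable | None = None,
) -> ThicknessDataset:
    """Read a participants x vertices thickness matrix (delimited text).

    The first column is participant_id; the rest are vertex columns.  When a
    ``cohort`` is supplied, rows are re-ordered to match its participant
    order (and must cover it).
    """
    df = pd.read_csv(path_matrix, sep=None, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    thickness = df.iloc[:, 1:].to_numpy(float)
    parcels = None
    if path_parcels is not None:
        parcels = np.loadtxt(path_parcels, dtype=int, ndmin=1)
        if parcels.size != thickness.shape[1]:
            raise FormatError(
                f"parcel file has {parcels.size} labels for {thickness.shape[1]} vertices"
            )
    hemi = None
    if path_hemisphere is not None:
        hemi = np.loadtxt(path_hemisphere, dtype=str, ndmin=1)
    ds = ThicknessDataset(ids, thickness, parcels, hemi)
    if cohort is not None:
        ds = ds.subset(cohort.ids)
    return ds


def write_thickness(ds: ThicknessDataset, path_matrix, path_parcels=None) -> None:
    cols = [f"v{i}" for i in range(ds.n_vertices)]
    df = pd.DataFrame(ds.thickness, columns=cols)
    df.insert(0, "participant_id", ds.participants)
    df.to_csv(path_matrix, sep="\t", index=False, float_format="%.17e")
    if path_parcels is not None and ds.parcel_map is not None:
        np.savetxt(path_parcels, ds.parcel_map, fmt="%d")


# ---------------------------------------------------------------------------
# flag report


def write_flag_report(flags: pd.DataFrame, path_tsv, path_json=None, meta: dict | None = None) -> None:
    """Write the per-participant flag table as TSV and optionally JSON."""
    flags.to_csv(path_tsv, sep="\t", index=False)
    if path_json is not None:
        payload = {"meta": meta or {}, "flags": flags.to_dict(orient="records")}
        Path(path_json).write_text(json.dumps(payload, indent=1, default=str))
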
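"""Domain types and on-disk formats for the emotional-picture paradigm.

The experiment: 54 affective pictures (18 negative / 18 neutral / 18
positive, crossed with 27 low- / 27 high-arousal), each shown for 6 s and
followed by a self-paced SAM rating period of up to 8 s, with successive
picture onsets 10-14 s apart, during a 470-volume EPI run at TR = 2 s.
Parcel signals follow a 246-region atlas with the left and right amygdala
flagged as connectivity seeds.

Events travel as BIDS-style tab-separated tables; parcel signals as a TSV
matrix (one row per volume, one column per ``parcel:voxel``) with a JSON
sidecar holding the sampling metadata.  A thin NIfTI adapter groups voxel
time series by an integer atlas label volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES", "AROUSAL_CLASSES", "GROUPS",
    "Trial", "EventTable", "SubjectRecord", "ParcelTimeSeries",
    "AtlasLabels", "MotionParams",
    "FormatError", "ValidationError",
    "read_events", "write_events",
    "read_parcel_matrix", "write_parcel_matrix",
    "read_nifti_with_atlas", "read_atlas_lookup", "default_atlas",
]

CATEGORIES = ("NEG", "NEU", "POS")
AROUSAL_CLASSES = ("LOW", "HIGH")
GROUPS = ("PATIENT", "HC")


class FormatError(ValueError):
    """A file does not follow the expected on-disk dialect."""


class ValidationError(ValueError):
    """Structurally readable data that violates a domain invariant."""


@dataclass(frozen=True)
class Trial:
    trial_id: int
    onset_s: float
    picture_duration_s: float
    category: str
    arousal_class: str
    valence_rating: int
    arousal_rating: int
    rating_onset_s: float
    rating_duration_s: float
    button_press_times_s: tuple[float, ...] = ()


@dataclass
class EventTable:
    """Per-trial timing, categories, SAM ratings and button presses."""

    trials: list[Trial]
    annotations: pd.DataFrame | None = None  # unknown columns, preserved

    def __post_init__(self) -> None:
        onsets = [t.onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("trial onsets must be strictly increasing")
        for t in self.trials:
            if t.category not in CATEGORIES:
                raise ValidationError(f"unknown category {t.category!r}")
            if t.arousal_class not in AROUSAL_CLASSES:
                raise ValidationError(f"unknown arousal class {t.arousal_class!r}")
            if not (1 <= t.valence_rating <= 9 and 1 <= t.arousal_rating <= 9):
                raise ValidationError("SAM ratings must lie in 1..9")
            if t.rating_duration_s > 8.0 + 1e-9:
                raise ValidationError("rating period exceeds 8 s")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for t in self.trials:
            out[t.category] += 1
        return out

    def arousal_counts(self) -> dict[str, int]:
        out = {a: 0 for a in AROUSAL_CLASSES}
        for t in self.trials:
            out[t.arousal_class] += 1
        return out

    @property
    def last_offset_s(self) -> float:
        return max(t.rating_onset_s + t.rating_duration_s for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "onset": t.onset_s, "duration": t.picture_duration_s,
                "trial_type": t.category, "arousal_class": t.arousal_class,
                "valence_rating": t.valence_rating,
                "arousal_rating": t.arousal_rating,
                "rating_onset": t.rating_onset_s,
                "rating_duration": t.rating_duration_s,
                "button_press_times": ";".join(f"{p:.4f}"
                                               for p in t.button_press_times_s),
            })
        frame = pd.DataFrame(rows)
        if self.annotations is not None:
            frame = pd.concat([frame, self.annotations.reset_index(drop=True)],
                              axis=1)
        return frame


@dataclass
class SubjectRecord:
    """One participant: group label, covariates and behavioral outcomes."""

    subject_id: str
    group: str
    sex: int          # 0/1 coding
    age: float
    bdi2: float
    iaps_set: str
    events: EventTable | None = None
    recognition_performance: float = float("nan")  # percent correct
    recognition_rt: float = float("nan")           # milliseconds

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        for name in ("age", "bdi2"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"covariate {name} must be finite")


@dataclass
class ParcelTimeSeries:
    """Voxel-level BOLD signals grouped into atlas parcels.

    ``data`` maps parcel id to a (n_volumes x n_voxels) array; volume k is
    sampled at k * tr_s from run start.
    """

    data: dict[int, np.ndarray]
    tr_s: float = 2.0
    highpass_applied: bool = False

    def __post_init__(self) -> None:
        lengths = {v.shape[0] for v in self.data.values()}
        if len(lengths) > 1:
            raise ValidationError("parcels disagree on the number of volumes")
        for pid, arr in self.data.items():
            if not np.isfinite(arr).all():
                raise ValidationError(f"parcel {pid} contains non-finite samples")

    @property
    def n_volumes(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def parcel_ids(self) -> list[int]:
        return sorted(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def check_covers(self, events: EventTable) -> None:
        if self.duration_s < events.last_offset_s:
            raise ValidationError("run shorter than the last event offset")


@dataclass(frozen=True)
class AtlasLabels:
    """Atlas lookup: parcel names, hemispheres and seed flags."""

    table: pd.DataFrame  # columns: parcel_id, name, hemisphere, is_seed

    def __post_init__(self) -> None:
        ids = self.table["parcel_id"]
        if ids.duplicated().any():
            raise ValidationError("duplicate parcel ids in atlas lookup")

    @property
    def seed_ids(self) -> list[int]:
        return self.table.loc[self.table["is_seed"].astype(bool),
                              "parcel_id"].astype(int).tolist()

    def name_of(self, parcel_id: int) -> str:
        hit = self.table.loc[self.table["parcel_id"] == parcel_id, "name"]
        return str(hit.iloc[0]) if len(hit) else str(parcel_id)


def default_atlas(n_parcels: int = 246,
                  seed_ids: Sequence[int] = (211, 212)) -> AtlasLabels:
    """A 246-parcel lookup with two amygdala seed parcels.

    Region names are synthetic placeholders; real analyses should supply
    the atlas lookup TSV of their parcellation.
    """
    rows = []
    for pid in range(1, n_parcels + 1):
        hemi = "L" if pid % 2 else "R"
        name = f"Amygdala ({hemi})" if pid in seed_ids else f"parcel_{pid:03d}"
        rows.append({"parcel_id": pid, "name": name, "hemisphere": hemi,
                     "is_seed": pid in seed_ids})
    return AtlasLabels(pd.DataFrame(rows))


@dataclass
class MotionParams:
    """Six rigid-body motion regressors: translations (mm), rotations (rad)."""

    values: np.ndarray  # n_volumes x 6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValidationError("motion parameters must be n_volumes x 6")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Events TSV (BIDS dialect)
# ---------------------------------------------------------------------------

_REQUIRED_EVENT_COLUMNS = ("onset", "duration", "trial_type",
                           "valence_rating", "arousal_rating")
_KNOWN_EVENT_COLUMNS = _REQUIRED_EVENT_COLUMNS + (
    "arousal_class", "rating_onset", "rating_duration", "button_press_times")


def read_events(path: str | Path) -> EventTable:
    """Read a BIDS-style events TSV into a validated :class:`EventTable`."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty events file") from exc
    missing = [c for c in _REQUIRED_EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    trials = []
    for i, row in frame.iterrows():
        presses: tuple[float, ...] = ()
        if "button_press_times" in frame.columns and pd.notna(row.get("button_press_times")):
            txt = str(row["button_press_times"]).strip()
            if txt:
                presses = tuple(float(x) for x in txt.split(";"))
        rating_onset = float(row.get("rating_onset",
                                     row["onset"] + row["duration"]))
        trials.append(Trial(
            trial_id=int(i),
            onset_s=float(row["onset"]),
            picture_duration_s=float(row["duration"]),
            category=str(row["trial_type"]),
            arousal_class=str(row.get("arousal_class", "LOW")),
            valence_rating=int(row["valence_rating"]),
            arousal_rating=int(row["arousal_rating"]),
            rating_onset_s=rating_onset,
            rating_duration_s=float(row.get("rating_duration", 0.0)),
            button_press_times_s=presses,
        ))
    extra = frame[[c for c in frame.columns if c not in _KNOWN_EVENT_COLUMNS]]
    annotations = extra if len(extra.columns) else None
    return EventTable(trials=trials, annotations=annotations)


def write_events(events: EventTable, path: str | Path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False,
                             float_format="%.12g")


# ---------------------------------------------------------------------------
# Parcel matrix TSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_parcel_matrix(path: str | Path) -> ParcelTimeSeries:
    """Read a parcel-by-time TSV (columns ``parcel:voxel``) with sidecar."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty parcel matrix") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows in parcel matrix") from exc
    if frame.empty:
        raise FormatError(f"{path}: parcel matrix has no rows")
    meta: dict = {"tr_s": 2.0}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    groups: dict[int, list[tuple[int, str]]] = {}
    for col in frame.columns:
        try:
            pid_s, vox_s = col.split(":")
            pid, vox = int(pid_s), int(vox_s)
        except ValueError as exc:
            raise FormatError(f"{path}: column {col!r} is not parcel:voxel") from exc
        groups.setdefault(pid, []).append((vox, col))
    data = {}
    for pid, cols in groups.items():
        cols.sort()
        data[pid] = frame[[c for _, c in cols]].to_numpy(dtype=float)
    ts = ParcelTimeSeries(data=data, tr_s=float(meta["tr_s"]),
                          highpass_applied=bool(meta.get("highpass_applied",
                                                         False)))
    declared = meta.get("n_volumes")
    if declared is not None and int(declared) != ts.n_volumes:
        raise ValidationError(
            f"{path}: sidecar declares {declared} volumes, file has {ts.n_volumes}")
    return ts


def write_parcel_matrix(ts: ParcelTimeSeries, path: str | Path) -> None:
    path = Path(path)
    columns = {}
    for pid in ts.parcel_ids:
        arr = ts.data[pid]
        for v in range(arr.shape[1]):
            columns[f"{pid}:{v}"] = arr[:, v]
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False,
                                 float_format="%.9g")
    _sidecar_path(path).write_text(json.dumps(
        {"tr_s": ts.tr_s, "n_volumes": ts.n_volumes,
         "highpass_applied": ts.highpass_applied}, indent=1))


# ---------------------------------------------------------------------------
# Optional NIfTI adapter
# ---------------------------------------------------------------------------

def read_atlas_lookup(path: str | Path) -> AtlasLabels:
    frame = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "name", "hemisphere", "is_seed"}
    if not required <= set(frame.columns):
        raise FormatError(f"{path}: atlas lookup needs columns {sorted(required)}")
    return AtlasLabels(frame)


def read_nifti_with_atlas(image_path: str | Path,
                          label_path: str | Path,
                          lookup: AtlasLabels | None = None,
                          tr_s: float | None = None) -> ParcelTimeSeries:
    """Group a 4D NIfTI's voxel time series by an integer atlas volume."""
    import nibabel as nib  # optional dependency, imported lazily
    import warnings

    img = nib.load(str(image_path))
    lab = nib.load(str(label_path))
    if img.shape[:3] != lab.shape:
        raise ValidationError("image and label volumes are on different grids")
    vol = np.asanyarray(img.dataobj, dtype=float)
    labels = np.asanyarray(lab.dataobj).astype(int)
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    data = {}
    known = set(lookup.table["parcel_id"].astype(int)) if lookup is not None else None
    for pid in np.unique(labels):
        if pid == 0:
            continue
        mask = labels == pid
        data[int(pid)] = vol[mask].T.copy()  # time x voxel
        if known is not None and int(pid) not in known:
            warnings.warn(f"label {pid} absent from atlas lookup; "
                          f"kept under its numeric name")
    return ParcelTimeSeries(data=data, tr_s=tr_s)
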
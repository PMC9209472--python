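"""Session data model, configuration, file I/O and the cell-variance filter.

A :class:`Session` bundles everything one miniscope recording contributes to
the analyses: a cells x samples df/F matrix on the neural timebase, a pose
table (nose / ear / tailbase xy at the same rate), per-cell spatial
footprints, and enclosure metadata.  Behavioral video is captured at 30 Hz
while the neural data are temporally downsampled by four, so the neural
timebase is fixed at 7.5 Hz and 30 Hz pose is block-averaged onto it during
loading.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

POSE_COLUMNS = ("nose_x", "nose_y", "ear_x", "ear_y", "tail_x", "tail_y")

MANIPULATIONS = ("none", "rotate0", "rotate180", "med_med", "med_short", "med_long")

CELL_TYPES = ("CAMK2A", "VGAT")


class LoadError(RuntimeError):
    """A session bundle is missing a component or cannot be parsed."""


class AlignmentError(RuntimeError):
    """Trace and pose sample counts cannot be reconciled."""


@dataclass
class SessionMeta:
    """Enclosure geometry and experiment labels for one session."""

    track_length_cm: float = 70.0
    track_length_half2_cm: float | None = None  # differs only for rescale sessions
    track_width_cm: float = 9.0
    manipulation: str = "none"
    cell_type: str = "CAMK2A"
    session_id: str = "session"
    day: int = 0

    def __post_init__(self) -> None:
        if self.manipulation not in MANIPULATIONS:
            raise ValueError(
                f"unknown manipulation {self.manipulation!r}; expected one of {MANIPULATIONS}"
            )
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.track_length_half2_cm is None:
            self.track_length_half2_cm = self.track_length_cm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class Session:
    """One aligned recording (or one manipulation half).

    ``traces`` is cells x samples df/F; ``pose`` is samples x 6 with columns
    ``nose_x, nose_y, ear_x, ear_y, tail_x, tail_y`` in cm on the neural
    timebase.  ``removed_interval`` is a half-open ``(start, stop)`` sample
    range excised around a mid-session manipulation; those samples are
    excluded from every downstream statistic.
    """

    traces: np.ndarray
    pose: np.ndarray
    sample_rate_hz: float = 7.5
    footprints: np.ndarray | None = None  # cells x H x W weighted images
    meta: SessionMeta = field(default_factory=SessionMeta)
    removed_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.pose = np.asarray(self.pose, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be cells x samples")
        if self.pose.shape != (self.traces.shape[1], len(POSE_COLUMNS)):
            raise AlignmentError(
                f"pose shape {self.pose.shape} does not match "
                f"{self.traces.shape[1]} neural samples x {len(POSE_COLUMNS)} columns"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def kept_samples(self) -> np.ndarray:
        """Boolean mask of samples outside the removed interval."""
        keep = np.ones(self.n_samples, dtype=bool)
        if self.removed_interval is not None:
            a, b = self.removed_interval
            keep[int(a) : int(b)] = False
        return keep

    def half_slices(self) -> tuple[slice, slice]:
        """Split a manipulation session at the removed interval.

        Without a removed interval the session splits at its midpoint.
        """
        if self.removed_interval is None:
            mid = self.n_samples // 2
            return slice(0, mid), slice(mid, self.n_samples)
        a, b = self.removed_interval
        return slice(0, int(a)), slice(int(b), self.n_samples)

    def subsession(self, sl: slice, track_length_cm: float | None = None) -> "Session":
        meta = SessionMeta.from_dict(self.meta.to_dict())
        if track_length_cm is not None:
            meta.track_length_cm = track_length_cm
            meta.track_length_half2_cm = track_length_cm
        return Session(
            traces=self.traces[:, sl],
            pose=self.pose[sl],
            sample_rate_hz=self.sample_rate_hz,
            footprints=self.footprints,
            meta=meta,
            removed_interval=None,
        )


@dataclass
class AnalysisConfig:
    """Fixed analysis constants.

    Defaults follow the conventions of the pipeline: a 3 cm/s movement
    threshold applied jointly to nose and tailbase speed, 0.5 s pose
    smoothing, 3.5 cm spatial bins, a 5x5-bin Gaussian map kernel with
    sd 0.85 bins, percentile-based permutation nulls, and 60 s decoding
    blocks separated by 10 s guards.
    """

    speed_threshold_cm_s: float = 3.0
    pose_smooth_window_s: float = 0.5
    spatial_bin_cm: float = 3.5
    map_smooth_kernel_bins: int = 5
    map_smooth_sd_bins: float = 0.85
    n_shuffles_place: int = 100
    n_shuffles_speed: int = 100
    n_shuffles_mapcorr: int = 1000
    field_threshold_sd: float = 1.5
    popevent_threshold_sd: float = 4.0
    deconv_threshold_sd: float = 3.0
    decode_block_s: float = 60.0
    decode_guard_s: float = 10.0
    decode_n_iter: int = 100
    percentile: float = 95.0
    peak_prominence_sd: float = 2.0
    match_min_iou: float = 0.3
    match_max_centroid_px: float = 8.0
    chance_shared_offsets: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_shuffles_place", "n_shuffles_speed", "n_shuffles_mapcorr",
                     "decode_n_iter", "map_smooth_kernel_bins"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class CellFilterResult:
    kept_indices: np.ndarray
    variances: np.ndarray
    outlier_flags: np.ndarray


def filter_cells(traces: np.ndarray) -> CellFilterResult:
    """Keep cells whose variance is >= 10% of the maximum non-outlier variance.

    Outliers are cells with variance above Q3 + 1.5 IQR of the across-cell
    variance distribution; they are flagged but always retained (the 10%
    floor references the largest *non-outlier* variance so that one huge
    cell does not silence the rest of the population).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 1:
        raise ValueError("need at least one cell")
    var = traces.var(axis=1)
    q1, q3 = np.percentile(var, [25, 75])
    outlier = var > q3 + 1.5 * (q3 - q1)
    non_outlier_var = var[~outlier]
    if non_outlier_var.size == 0 or non_outlier_var.max() == 0.0:
        if var.max() == 0.0:
            warnings.warn("all traces are constant; no cells kept")
            return CellFilterResult(np.array([], dtype=int), var, outlier)
        ref = var.max()
    else:
        ref = non_outlier_var.max()
    kept = np.flatnonzero(var >= 0.1 * ref)
    return CellFilterResult(kept, var, outlier)


# ---------------------------------------------------------------------------
# container I/O


def _resample_pose(pose: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a high-rate pose table onto the neural timebase."""
    n = (pose.shape[0] // factor) * factor
    return pose[:n].reshape(-1, factor, pose.shape[1]).mean(axis=1)


def save_session(session: Session, path: str | Path) -> Path:
    """Write a session to a single HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("pose", data=session.pose)
        if session.footprints is not None:
            f.create_dataset("footprints", data=session.footprints)
        meta = dict(session.meta.to_dict())
        meta["sample_rate_hz"] = session.sample_rate_hz
        if session.removed_interval is not None:
            meta["removed_interval"] = list(session.removed_interval)
        f.attrs["meta"] = json.dumps(meta, sort_keys=True)
    return path


def _load_h5(path: Path) -> Session:
    with h5py.File(path, "r") as f:
        for name in ("traces", "pose"):
            if name not in f:
                raise LoadError(f"container {path} lacks dataset /{name}")
        traces = f["traces"][()]
        pose = f["pose"][()]
        footprints = f["footprints"][()] if "footprints" in f else None
        meta = json.loads(f.attrs.get("meta", "{}"))
    return _assemble(traces, pose, footprints, meta, path)


def _load_csv_bundle(path: Path) -> Session:
    traces_f = path / "traces.csv"
    pose_f = path / "pose.csv"
    meta_f = path / "meta.json"
    if not traces_f.exists():
        raise LoadError(f"bundle {path} is missing traces.csv")
    if not pose_f.exists():
        raise AlignmentError(f"bundle {path} is missing pose.csv")
    traces = np.loadtxt(traces_f, delimiter=",", ndmin=2)
    pose_tab = np.loadtxt(pose_f, delimiter=",", skiprows=1, ndmin=2)
    pose = pose_tab[:, 1:]  # first column is the sample index
    meta = json.loads(meta_f.read_text()) if meta_f.exists() else {}
    return _assemble(traces, pose, None, meta, path)


def _assemble(traces, pose, footprints, meta: dict, origin) -> Session:
    sample_rate = float(meta.pop("sample_rate_hz", 7.5))
    pose_rate = float(meta.pop("pose_rate_hz", sample_rate))
    removed = meta.pop("removed_interval", None)
    n = traces.shape[1]
    if pose.shape[0] != n:
        ratio = pose.shape[0] / n
        factor = int(round(ratio))
        if factor < 1 or abs(ratio - factor) > 1e-9:
            raise AlignmentError(
                f"{origin}: pose has {pose.shape[0]} samples for {n} neural "
                "samples; not an integer decimation"
            )
        pose = _resample_pose(pose, factor)
        if pose.shape[0] != n:
            raise AlignmentError(
                f"{origin}: pose length {pose.shape[0]} after {factor}:1 "
                f"averaging still differs from {n} neural samples"
            )
    else:
        pose_rate = sample_rate
    del pose_rate
    session = Session(
        traces=traces,
        pose=pose,
        sample_rate_hz=sample_rate,
        footprints=footprints,
        meta=SessionMeta.from_dict(meta),
        removed_interval=tuple(removed) if removed is not None else None,
    )
    return session


def load_session(path: str | Path) -> Session:
    """Load a session from an HDF5 container or a CSV/JSON bundle directory."""
    path = Path(path)
    if path.is_dir():
        return _load_csv_bundle(path)
    if not path.exists():
        raise LoadError(f"no session at {path}")
    return _load_h5(path)
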
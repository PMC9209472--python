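"""Activity maps, spatial mutual information and place-field geometry.

Place coding is quantified by the mutual information between binned df/F and
binned track position,

    I(X;Y) = sum_xy p(x,y) log2[ p(x,y) / (p(x) p(y)) ],

computed over movement-masked samples only.  Position is binned at 3.5 cm
along the track length; df/F is binned by Sturges' rule (ceil(1 + log2 n)
bins over the masked samples).  A cell is a place cell when its MI exceeds
the 95th percentile of a null distribution built from fixed circular shifts
of the trace (increments of T/100 samples; identity shifts excluded).

Activity maps are occupancy-normalized mean df/F on a 3.5 x 3.5 cm grid,
optionally smoothed with a 5x5-bin Gaussian kernel (sd 0.85 bins); place
fields are 4-connected components of smoothed-map bins exceeding the
occupied-bin mean by 1.5 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .behavior import BehaviorSeries, analyze_behavior
from .io_core import AnalysisConfig, Session
from .nulls import cyclic_offsets, upper_threshold


def sturges_bins(n: int) -> int:
    """Sturges' bin count, ceil(1 + log2 n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(np.ceil(1.0 + np.log2(n)))


def n_position_bins(track_length_cm: float, bin_cm: float = 3.5) -> int:
    return max(int(np.ceil(track_length_cm / bin_cm - 1e-9)), 1)


def bin_position(x: np.ndarray, track_length_cm: float, bin_cm: float = 3.5) -> np.ndarray:
    nx = n_position_bins(track_length_cm, bin_cm)
    return np.clip((np.asarray(x) / bin_cm).astype(int), 0, nx - 1)


def _bin_values(y: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins over [min, max]; top-edge values go to the last bin."""
    lo, hi = y.min(), y.max()
    if hi <= lo:
        return np.zeros(y.size, dtype=int)
    return np.minimum(((y - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)


@dataclass
class BinnedJoint:
    """Joint histogram of binned position and binned df/F."""

    counts: np.ndarray  # nx x ny
    n: int

    @property
    def joint(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def p_x(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def binned_joint(
    trace: np.ndarray,
    x_position: np.ndarray,
    mask: np.ndarray,
    track_length_cm: float,
    bin_cm: float = 3.5,
) -> BinnedJoint:
    y = np.asarray(trace, dtype=float)[mask]
    xb = bin_position(np.asarray(x_position)[mask], track_length_cm, bin_cm)
    if y.size < 2:
        raise ValueError("need at least two movement-masked samples")
    ny = sturges_bins(y.size)
    yb = _bin_values(y, ny)
    nx = n_position_bins(track_length_cm, bin_cm)
    counts = np.bincount(xb * ny + yb, minlength=nx * ny).reshape(nx, ny)
    return BinnedJoint(counts=counts, n=y.size)


def mutual_information_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a joint probability table; zero cells contribute 0."""
    p = np.asarray(joint, dtype=float)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(terms[nz].sum())


def mutual_information(
    trace: np.ndarray,
    x_position: np.ndarray,
    mask: np.ndarray,
    track_length_cm: float,
    bin_cm: float = 3.5,
) -> float:
    """Spatial MI (bits) of one trace over movement-masked samples."""
    xb_all = bin_position(np.asarray(x_position)[mask], track_length_cm, bin_cm)
    if np.unique(xb_all).size < 2:
        warnings.warn("single occupied position bin; MI set to 0")
        return 0.0
    bj = binned_joint(trace, x_position, mask, track_length_cm, bin_cm)
    return mutual_information_from_joint(bj.joint)


# ---------------------------------------------------------------------------
# activity maps and place fields


@dataclass
class ActivityMap:
    """Occupancy-normalized mean-df/F map, shape (n_y_bins, n_x_bins)."""

    values: np.ndarray
    occupancy: np.ndarray  # movement-masked sample counts per bin
    bin_cm: float
    track_length_cm: float
    smoothed: bool = False

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0

    @property
    def x_centers_cm(self) -> np.ndarray:
        return (np.arange(self.values.shape[1]) + 0.5) * self.bin_cm


def _gaussian_kernel(size: int, sd: float) -> np.ndarray:
    half = size // 2
    g = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def smooth_map(raw: ActivityMap, kernel_bins: int = 5, sd_bins: float = 0.85) -> ActivityMap:
    """Gaussian smoothing with edge renormalization over occupied bins."""
    k = _gaussian_kernel(kernel_bins, sd_bins)
    occ = raw.occupied.astype(float)
    vals = np.where(raw.occupied, raw.values, 0.0)
    num = ndimage.convolve(vals, k, mode="constant", cval=0.0)
    den = ndimage.convolve(occ, k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, np.nan)
    return ActivityMap(sm, raw.occupancy.copy(), raw.bin_cm, raw.track_length_cm, smoothed=True)


def compute_activity_map(
    trace: np.ndarray,
    behavior: BehaviorSeries,
    track_length_cm: float,
    track_width_cm: float,
    config: AnalysisConfig | None = None,
    smooth: bool = True,
) -> ActivityMap:
    """Mean df/F per 3.5 x 3.5 cm bin over movement-masked samples."""
    config = config or AnalysisConfig()
    mask = behavior.movement_mask
    if not mask.any():
        raise ValueError("movement mask is empty; no samples enter the map")
    bin_cm = config.spatial_bin_cm
    nx = n_position_bins(track_length_cm, bin_cm)
    ny = n_position_bins(track_width_cm, bin_cm)
    xb = np.clip((behavior.x[mask] / bin_cm).astype(int), 0, nx - 1)
    yb = np.clip((behavior.y[mask] / bin_cm).astype(int), 0, ny - 1)
    code = yb * nx + xb
    occupancy = np.bincount(code, minlength=ny * nx).reshape(ny, nx)
    sums = np.bincount(code, weights=np.asarray(trace, float)[mask], minlength=ny * nx)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(occupancy > 0, sums.reshape(ny, nx) / occupancy, np.nan)
    raw = ActivityMap(values, occupancy, bin_cm, track_length_cm, smoothed=False)
    if not smooth:
        return raw
    return smooth_map(raw, config.map_smooth_kernel_bins, config.map_smooth_sd_bins)


@dataclass
class PlaceField:
    center_cm: float
    width_cm: float
    size_cm2: float
    n_bins: int
    peak_value: float
    bins: np.ndarray  # (row, col) indices


def detect_place_fields(smoothed: ActivityMap, threshold_sd: float = 1.5) -> list[PlaceField]:
    """4-connected supra-threshold components of a smoothed activity map.

    Threshold = mean + ``threshold_sd`` x SD over occupied bins.  Field size
    is bin area x bin count; width is the x extent (first to last column
    spanned); the center is the x of the field's maximum bin.  Fields are
    sorted by descending peak value.
    """
    occ = smoothed.occupied
    vals = smoothed.values
    pool = vals[occ]
    if pool.size == 0:
        return []
    thr = pool.mean() + threshold_sd * pool.std()
    supra = np.zeros_like(occ)
    supra[occ] = vals[occ] > thr
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(supra, structure=structure)
    fields: list[PlaceField] = []
    bin_cm = smoothed.bin_cm
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        comp_vals = vals[rows, cols]
        peak = comp_vals.argmax()
        fields.append(
            PlaceField(
                center_cm=float((cols[peak] + 0.5) * bin_cm),
                width_cm=float((cols.max() - cols.min() + 1) * bin_cm),
                size_cm2=float(bin_cm * bin_cm * rows.size),
                n_bins=int(rows.size),
                peak_value=float(comp_vals[peak]),
                bins=np.column_stack([rows, cols]),
            )
        )
    fields.sort(key=lambda f: -f.peak_value)
    return fields


# ---------------------------------------------------------------------------
# place-cell classification


@dataclass
class PlaceCellResult:
    mi: float
    null_mi: np.ndarray
    threshold: float
    is_place_cell: bool
    fields: list[PlaceField] = field(default_factory=list)
    classifiable: bool = True

    @property
    def field_count(self) -> int:
        return len(self.fields)

    @property
    def primary_field(self) -> PlaceField | None:
        return self.fields[0] if self.fields else None


def _mi_with_shifts(
    trace: np.ndarray,
    xb_masked: np.ndarray,
    mask_idx: np.ndarray,
    offsets: np.ndarray,
    n_x_bins: int,
) -> np.ndarray:
    """MI of the trace and of each circularly shifted copy (vectorized).

    Row 0 is the unshifted trace; rows 1.. follow ``offsets``.  Shifting
    moves the whole trace before masking, so each shift re-bins its own
    masked df/F values with its own Sturges edges.
    """
    T = trace.size
    m = mask_idx.size
    ny = sturges_bins(m)
    all_offsets = np.concatenate([[0], offsets])
    gather = (mask_idx[None, :] - all_offsets[:, None]) % T
    Y = trace[gather]  # (S, m)
    lo = Y.min(axis=1, keepdims=True)
    hi = Y.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    yb = np.minimum(((Y - lo) / span * ny).astype(int), ny - 1)
    S = all_offsets.size
    code = (np.arange(S)[:, None] * (n_x_bins * ny)) + xb_masked[None, :] * ny + yb
    counts = np.bincount(code.ravel(), minlength=S * n_x_bins * ny)
    p = counts.reshape(S, n_x_bins, ny) / m
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (px * py)), 0.0)
    return terms.sum(axis=(1, 2))


def classify_place_cells(
    session: Session,
    config: AnalysisConfig | None = None,
    behavior: BehaviorSeries | None = None,
    with_fields: bool = True,
) -> list[PlaceCellResult]:
    """Classify every cell of a session by the circular-shift MI test.

    The null is deterministic: the trace is circularly shifted by fixed
    increments of T/100 (identity shifts excluded, leaving 99 values) and
    MI recomputed after applying the movement mask.
    """
    config = config or AnalysisConfig()
    behavior = behavior or analyze_behavior(session, config)
    mask_idx = np.flatnonzero(behavior.movement_mask)
    L = session.meta.track_length_cm
    nx = n_position_bins(L, config.spatial_bin_cm)
    results: list[PlaceCellResult] = []
    if mask_idx.size < 100:
        empty = np.empty(0)
        return [
            PlaceCellResult(np.nan, empty, np.nan, False, [], classifiable=False)
            for _ in range(session.n_cells)
        ]
    xb_masked = bin_position(behavior.x[mask_idx], L, config.spatial_bin_cm)
    offsets = cyclic_offsets(session.n_samples, config.n_shuffles_place)
    for trace in session.traces:
        mis = _mi_with_shifts(trace, xb_masked, mask_idx, offsets, nx)
        mi, null = float(mis[0]), mis[1:]
        thr = upper_threshold(null, config.percentile)
        is_pc = mi > thr
        fields: list[PlaceField] = []
        if with_fields and is_pc:
            amap = compute_activity_map(
                trace, behavior, L, session.meta.track_width_cm, config, smooth=True
            )
            fields = detect_place_fields(amap, config.field_threshold_sd)
        results.append(PlaceCellResult(mi, null, thr, bool(is_pc), fields))
    return results
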
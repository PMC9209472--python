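"""Within-session manipulation analyses: rotation thirds, map correlations
across halves (with rescaling), and place-field width change.

2-D activity maps are flattened to 1-D profiles by taking the maximum over
the width dimension at each position along the track; profiles from halves
of different track lengths are compared after linearly resampling the
second-half profile onto the first half's relative positions.  Correlations
are Spearman over pairwise-complete bins, with a chance level from 1000
circular shuffles of the second-half profiles (a shared offset per
iteration preserves across-cell structure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import analyze_behavior
from .io_core import AnalysisConfig, Session
from .nulls import upper_threshold
from .spatial_coding import (
    ActivityMap,
    PlaceCellResult,
    PlaceField,
    classify_place_cells,
    compute_activity_map,
)

ROTATION_CATEGORIES = ("rotate", "non_rotate", "middle_excluded", "lost")


def flatten_map(amap: ActivityMap) -> np.ndarray:
    """Column-wise maximum over occupied bins; empty columns become NaN."""
    vals = np.where(amap.occupied, amap.values, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        profile = np.nanmax(vals, axis=0)
    return profile


def _resample_profile(profile: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation onto matched relative positions."""
    n_in = profile.size
    if n_in == n_out:
        return profile.copy()
    pos_in = (np.arange(n_in) + 0.5) / n_in
    pos_out = (np.arange(n_out) + 0.5) / n_out
    finite = np.isfinite(profile)
    if finite.sum() < 2:
        return np.full(n_out, np.nan)
    return np.interp(pos_out, pos_in[finite], profile[finite])


def rate_map_correlation(profile1: np.ndarray, profile2: np.ndarray) -> float:
    """Spearman r of two 1-D profiles, resampling the second if lengths differ."""
    p1 = np.asarray(profile1, dtype=float)
    p2 = np.asarray(profile2, dtype=float)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("profiles must be nonempty")
    if p2.size != p1.size:
        p2 = _resample_profile(p2, p1.size)
    ok = np.isfinite(p1) & np.isfinite(p2)
    if ok.sum() < 3:
        return np.nan
    return float(stats.spearmanr(p1[ok], p2[ok]).statistic)


def correlation_chance(
    profiles1: list[np.ndarray],
    profiles2: list[np.ndarray],
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    percentile: float = 95.0,
    shared_offsets: bool = True,
) -> float:
    """95th percentile of the pooled shuffle null of map correlations.

    Per iteration every second-half profile is circularly shifted (after
    resampling to its partner's length) and all pairwise-matched
    correlations recomputed; shifts are shared across cells within an
    iteration by default.
    """
    if len(profiles1) == 0:
        raise ValueError("need at least one cell")
    rng = rng or np.random.default_rng(0)
    pairs = []
    for p1, p2 in zip(profiles1, profiles2):
        p1 = np.asarray(p1, float)
        p2 = np.asarray(p2, float)
        if p2.size != p1.size:
            p2 = _resample_profile(p2, p1.size)
        pairs.append((p1, p2))
    null = []
    for _ in range(n_iter):
        shared = rng.integers(1, max(pairs[0][0].size, 2))
        for p1, p2 in pairs:
            off = shared % p1.size if shared_offsets else rng.integers(1, p1.size)
            r = rate_map_correlation(p1, np.roll(p2, off))
            if np.isfinite(r):
                null.append(r)
    return upper_threshold(np.asarray(null), percentile)


def classify_rotation(
    fields_half1: list[PlaceField],
    fields_half2: list[PlaceField],
    track_length_cm: float,
    is_place_half2: bool = True,
    track_length_half2_cm: float | None = None,
) -> str:
    """Thirds-based rotation category for a half-1 place cell.

    The caller guarantees the cell is a place cell in half 1.  Cells whose
    primary field center lies in the middle third are excluded; cells that
    are not place cells (or have no field) in half 2 are 'lost'; otherwise
    the half-2 primary center decides rotate (opposite outer third) vs
    non_rotate (same outer third), with intermediate landings counted as
    'lost' from the rotate/non-rotate tally.
    """
    L = float(track_length_cm)
    if L <= 0:
        raise ValueError("track length must be positive")
    if not fields_half1:
        raise ValueError("half-1 place cell must have a primary field")
    c1 = fields_half1[0].center_cm
    third1 = min(int(3 * c1 / L), 2)
    if third1 == 1:
        return "middle_excluded"
    if not is_place_half2 or not fields_half2:
        return "lost"
    c2 = fields_half2[0].center_cm
    # rescaled halves compare thirds in relative coordinates
    L2 = float(track_length_half2_cm) if track_length_half2_cm else L
    third2 = min(int(3 * c2 / L2), 2)
    if third2 == 2 - third1:
        return "rotate"
    if third2 == third1:
        return "non_rotate"
    return "lost"


@dataclass
class HalfPairCell:
    """Per-cell comparison of the two halves of a manipulation session."""

    profile1: np.ndarray
    profile2: np.ndarray
    map_r: float
    rotation: str | None  # None when not a half-1 place cell
    width_change_cm: float | None  # place cell in both halves only
    is_place_1: bool
    is_place_2: bool


@dataclass
class HalfPairResult:
    cells: list[HalfPairCell]
    chance_threshold: float
    place1: list[PlaceCellResult]
    place2: list[PlaceCellResult]

    def rotation_fractions(self) -> dict[str, float]:
        """Rotate / non-rotate fractions over half-1 outer-third place cells."""
        cats = [c.rotation for c in self.cells if c.rotation is not None]
        outer = [c for c in cats if c != "middle_excluded"]
        n = len(outer)
        out = {k: 0.0 for k in ("rotate", "non_rotate", "lost")}
        if n:
            for k in out:
                out[k] = sum(c == k for c in outer) / n
        out["n_outer"] = n
        out["n_middle_excluded"] = sum(c == "middle_excluded" for c in cats)
        return out

    def width_changes(self) -> np.ndarray:
        return np.array(
            [c.width_change_cm for c in self.cells if c.width_change_cm is not None]
        )

    def map_correlations(self, place1_only: bool = True) -> np.ndarray:
        rs = [
            c.map_r
            for c in self.cells
            if np.isfinite(c.map_r) and (c.is_place_1 or not place1_only)
        ]
        return np.asarray(rs)


def field_width_change(
    place1: PlaceCellResult, place2: PlaceCellResult
) -> float | None:
    """Primary-field width change (half 2 minus half 1, cm).

    Defined only when the cell is independently a place cell with at least
    one field in each half.
    """
    if not (place1.is_place_cell and place2.is_place_cell):
        return None
    if not (place1.fields and place2.fields):
        return None
    return place2.fields[0].width_cm - place1.fields[0].width_cm


def analyze_half_pair(
    session: Session,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> HalfPairResult:
    """Full two-half analysis of a rotation or rescaling session."""
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    sl1, sl2 = session.half_slices()
    half1 = session.subsession(sl1, session.meta.track_length_cm)
    half2 = session.subsession(sl2, session.meta.track_length_half2_cm)
    beh1 = analyze_behavior(half1, config)
    beh2 = analyze_behavior(half2, config)
    place1 = classify_place_cells(half1, config, beh1)
    place2 = classify_place_cells(half2, config, beh2)
    cells: list[HalfPairCell] = []
    profiles1, profiles2 = [], []
    for i in range(session.n_cells):
        m1 = compute_activity_map(
            half1.traces[i], beh1, half1.meta.track_length_cm,
            half1.meta.track_width_cm, config, smooth=True,
        )
        m2 = compute_activity_map(
            half2.traces[i], beh2, half2.meta.track_length_cm,
            half2.meta.track_width_cm, config, smooth=True,
        )
        p1, p2 = flatten_map(m1), flatten_map(m2)
        profiles1.append(p1)
        profiles2.append(p2)
        r = rate_map_correlation(p1, p2)
        rotation = None
        if place1[i].is_place_cell and place1[i].fields:
            rotation = classify_rotation(
                place1[i].fields,
                place2[i].fields,
                half1.meta.track_length_cm,
                place2[i].is_place_cell,
                half2.meta.track_length_cm,
            )
        cells.append(
            HalfPairCell(
                profile1=p1,
                profile2=p2,
                map_r=r,
                rotation=rotation,
                width_change_cm=field_width_change(place1[i], place2[i]),
                is_place_1=place1[i].is_place_cell,
                is_place_2=place2[i].is_place_cell,
            )
        )
    chance = correlation_chance(
        profiles1,
        profiles2,
        n_iter=config.n_shuffles_mapcorr,
        rng=rng,
        percentile=config.percentile,
        shared_offsets=config.chance_shared_offsets,
    )
    return HalfPairResult(cells=cells, chance_threshold=chance, place1=place1, place2=place2)
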
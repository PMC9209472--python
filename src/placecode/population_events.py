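"""Population coactivity ("sharp-wave-like") event detection.

Per-cell binary events come from a simple deconvolution: samples where the
positive first difference of the trace exceeds a robust multiple of the
differenced-trace noise scale, with adjacent supra-threshold samples merged
onto the first (onsets).  Population events are samples where the number of
coactive cells reaches mean + 4 SD of the session's coactivity series;
contiguous supra-threshold samples are merged into single events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorSeries


def deconvolve_events(trace: np.ndarray, threshold_sd: float = 3.0) -> np.ndarray:
    """Binary event series (onsets) from thresholded positive differences."""
    trace = np.asarray(trace, dtype=float)
    d = np.diff(trace)
    mad = np.median(np.abs(d - np.median(d)))
    scale = 1.4826 * mad
    if scale == 0.0:
        scale = d.std() or np.inf
    supra = d > threshold_sd * scale
    events = np.zeros(trace.size, dtype=bool)
    # merge runs of supra-threshold rises onto their first sample
    onset = supra & ~np.concatenate([[False], supra[:-1]])
    events[1:][onset] = True
    return events


def event_raster(traces: np.ndarray, threshold_sd: float = 3.0) -> np.ndarray:
    return np.stack([deconvolve_events(t, threshold_sd) for t in np.atleast_2d(traces)])


@dataclass
class PopulationEventSet:
    event_samples: np.ndarray        # one representative (peak) sample per merged event
    event_slices: list[tuple[int, int]]  # half-open supra-threshold runs
    supra_samples: np.ndarray        # all supra-threshold samples (unmerged count)
    coactivity: np.ndarray
    threshold: float
    participation: np.ndarray        # bool per cell

    @property
    def n_events(self) -> int:
        return self.event_samples.size

    @property
    def n_supra_samples(self) -> int:
        return self.supra_samples.size


def detect_population_events(
    raster: np.ndarray, threshold_sd: float = 4.0
) -> PopulationEventSet:
    """Events where the coactive-cell count reaches mean + ``threshold_sd`` SD."""
    raster = np.atleast_2d(np.asarray(raster, dtype=bool))
    if raster.shape[0] < 2:
        raise ValueError("need at least two cells")
    co = raster.sum(axis=0).astype(float)
    sd = co.std()
    if sd == 0.0:
        return PopulationEventSet(
            np.empty(0, int), [], np.empty(0, int), co, np.inf,
            np.zeros(raster.shape[0], bool),
        )
    thr = co.mean() + threshold_sd * sd
    supra = co >= thr
    supra_idx = np.flatnonzero(supra)
    slices: list[tuple[int, int]] = []
    peaks: list[int] = []
    if supra_idx.size:
        breaks = np.flatnonzero(np.diff(supra_idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks, [supra_idx.size - 1]])
        for a, b in zip(starts, stops):
            lo, hi = supra_idx[a], supra_idx[b] + 1
            slices.append((int(lo), int(hi)))
            peaks.append(int(lo + np.argmax(co[lo:hi])))
    participation = raster[:, supra_idx].any(axis=1) if supra_idx.size else np.zeros(
        raster.shape[0], bool
    )
    return PopulationEventSet(
        event_samples=np.asarray(peaks, dtype=int),
        event_slices=slices,
        supra_samples=supra_idx,
        coactivity=co,
        threshold=float(thr),
        participation=participation,
    )


@dataclass
class EventSpeedProfile:
    mean_speed_cm_s: float
    event_speeds: np.ndarray
    speed_grid: np.ndarray
    cumulative_percent: np.ndarray


def event_speed_profile(
    events: PopulationEventSet, behavior: BehaviorSeries, grid_step: float = 1.0
) -> EventSpeedProfile:
    """Mean speed during events and cumulative % of events by speed."""
    if events.n_events == 0:
        raise ValueError("no population events to profile")
    speeds = np.array(
        [behavior.speed[a:b].mean() for a, b in events.event_slices]
    )
    top = max(float(np.ceil(speeds.max())) + grid_step, grid_step)
    grid = np.arange(grid_step, top + grid_step / 2, grid_step)
    cum = np.array([(speeds <= g).mean() * 100.0 for g in grid])
    return EventSpeedProfile(
        mean_speed_cm_s=float(speeds.mean()),
        event_speeds=speeds,
        speed_grid=grid,
        cumulative_percent=cum,
    )
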
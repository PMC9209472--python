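"""Cross-day cell matching from spatial footprints, coregistration
validation, turnover, and across-day stability of place and speed coding.

Matching is deterministic: footprint fields are first aligned by the rigid
integer translation that maximizes the cross-correlation of the two summed
footprint images, footprints are binarized at half their peak weight, and
pairs are accepted greedily by descending intersection-over-union subject
to IoU and centroid-distance thresholds, one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import analyze_behavior
from .io_core import AnalysisConfig, Session
from .nulls import upper_threshold
from .remapping import flatten_map, rate_map_correlation
from .spatial_coding import classify_place_cells, compute_activity_map
from .speed_coding import classify_speed_cells
from .trace_metrics import population_peak_stats


@dataclass
class Matching:
    pairs: np.ndarray            # (n_pairs, 2): day-i index, day-j index
    iou: np.ndarray              # per accepted pair
    centroid_distance_px: np.ndarray
    unmatched_i: np.ndarray
    unmatched_j: np.ndarray
    shift_px: tuple[int, int]    # applied rigid translation (dy, dx)


def _binarize(footprints: np.ndarray) -> np.ndarray:
    fp = np.asarray(footprints, dtype=float)
    peaks = fp.reshape(fp.shape[0], -1).max(axis=1)
    peaks = np.where(peaks > 0, peaks, 1.0)
    return fp > 0.5 * peaks[:, None, None]


def _centroids(masks: np.ndarray) -> np.ndarray:
    n = masks.shape[0]
    out = np.zeros((n, 2))
    for i, m in enumerate(masks):
        ys, xs = np.nonzero(m)
        if ys.size:
            out[i] = ys.mean(), xs.mean()
    return out


def _correlation_peaks(
    sum_i: np.ndarray, sum_j: np.ndarray, max_shift: int, whiten: bool, k: int
) -> list[tuple[int, int]]:
    """Top-k integer shifts of a (possibly whitened) cross-correlation."""
    fi = np.fft.rfft2(sum_i)
    fj = np.fft.rfft2(sum_j)
    cross = fi * np.conj(fj)
    if whiten:  # phase correlation
        mag = np.abs(cross)
        cross = cross / (mag + 1e-9 * (mag.max() or 1.0))
    xc = np.fft.fftshift(np.fft.irfft2(cross, s=sum_i.shape))
    cy, cx = sum_i.shape[0] // 2, sum_i.shape[1] // 2
    win = xc[cy - max_shift : cy + max_shift + 1, cx - max_shift : cx + max_shift + 1]
    order = np.argsort(win, axis=None)[::-1][:k]
    return [
        (int(dy - max_shift), int(dx - max_shift))
        for dy, dx in (np.unravel_index(o, win.shape) for o in order)
    ]


def _candidate_shifts(sum_i: np.ndarray, sum_j: np.ndarray, max_shift: int = 20) -> list:
    """Plausible rigid translations of field j onto field i.

    Neither estimator alone is reliable here: plain cross-correlation of
    scattered-blob images is nearly flat and can be won by accidental
    overlaps of non-shared cells, while phase correlation loses its peak
    when per-cell jitter breaks phase coherence.  Both contribute
    candidates (plus the identity), and the caller keeps whichever shift
    yields the best actual matching.
    """
    cands = [(0, 0)]
    cands += _correlation_peaks(sum_i, sum_j, max_shift, whiten=True, k=3)
    cands += _correlation_peaks(sum_i, sum_j, max_shift, whiten=False, k=2)
    seen: list = []
    for c in cands:
        if c not in seen:
            seen.append(c)
    return seen


def match_cells(
    footprints_i: np.ndarray,
    footprints_j: np.ndarray,
    config: AnalysisConfig | None = None,
    align: bool = True,
) -> Matching:
    """Greedy one-to-one footprint matching between two days."""
    config = config or AnalysisConfig()
    fi = np.asarray(footprints_i, dtype=float)
    fj = np.asarray(footprints_j, dtype=float)
    ni, nj = fi.shape[0], fj.shape[0]
    if ni == 0 or nj == 0:
        return Matching(
            np.empty((0, 2), int), np.empty(0), np.empty(0),
            np.arange(ni), np.arange(nj), (0, 0),
        )
    bi = _binarize(fi)
    bj = _binarize(fj)
    shift = (0, 0)
    if align:
        ci0 = _centroids(bi)
        cj0 = _centroids(bj)
        # score with a tighter radius than the acceptance threshold:
        # accidental centroid pairs at the full radius are common enough
        # on dense fields to outvote the true displacement
        thr = 0.5 * config.match_max_centroid_px

        def shift_score(s):
            # greedy one-to-one centroid pairs within threshold; more pairs
            # win, ties break toward tighter alignment
            d = np.linalg.norm(ci0[:, None, :] - (cj0 + np.asarray(s))[None, :, :], axis=2)
            count = 0
            total = 0.0
            while True:
                k = np.argmin(d)
                i, j = divmod(int(k), d.shape[1])
                if not np.isfinite(d[i, j]) or d[i, j] > thr:
                    return (count, -total)
                count += 1
                total += d[i, j]
                d[i, :] = np.inf
                d[:, j] = np.inf

        cands = _candidate_shifts(fi.sum(axis=0), fj.sum(axis=0))
        shift = max(cands, key=shift_score)
        bj = np.roll(bj, shift, axis=(1, 2))
    flat_i = bi.reshape(ni, -1).astype(np.float32)
    flat_j = bj.reshape(nj, -1).astype(np.float32)
    inter = flat_i @ flat_j.T
    area_i = flat_i.sum(axis=1)[:, None]
    area_j = flat_j.sum(axis=1)[None, :]
    union = area_i + area_j - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    ci = _centroids(bi)
    cj = _centroids(bj)
    dist = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
    cand = (iou >= config.match_min_iou) & (dist <= config.match_max_centroid_px)
    order = np.argsort(-iou, axis=None)
    used_i = np.zeros(ni, bool)
    used_j = np.zeros(nj, bool)
    pairs, pair_iou, pair_dist = [], [], []
    for flat in order:
        i, j = divmod(int(flat), nj)
        if not cand[i, j] or iou[i, j] <= 0:
            continue
        if used_i[i] or used_j[j]:
            continue
        used_i[i] = used_j[j] = True
        pairs.append((i, j))
        pair_iou.append(iou[i, j])
        pair_dist.append(dist[i, j])
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return Matching(
        pairs=pairs_arr,
        iou=np.asarray(pair_iou),
        centroid_distance_px=np.asarray(pair_dist),
        unmatched_i=np.flatnonzero(~used_i),
        unmatched_j=np.flatnonzero(~used_j),
        shift_px=shift,
    )


def turnover_fraction(matching: Matching, n_cells_i: int, n_cells_j: int) -> float:
    """Matched pairs over the mean of the two sessions' cell counts."""
    if n_cells_i <= 0 or n_cells_j <= 0:
        raise ValueError("cell counts must be positive")
    return matching.pairs.shape[0] / ((n_cells_i + n_cells_j) / 2.0)


@dataclass
class CoregistrationValidation:
    amplitude_r: float
    amplitude_chance: float
    pnr_r: float
    pnr_chance: float
    n_pairs: int
    low_power: bool


def _shuffle_chance(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
    n_iter: int = 1000, percentile: float = 95.0,
) -> float:
    null = np.array(
        [stats.spearmanr(a, rng.permutation(b)).statistic for _ in range(n_iter)]
    )
    return upper_threshold(null, percentile)


def coregistration_validation(
    session_i: Session,
    session_j: Session,
    matching: Matching,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    n_iter: int = 1000,
) -> CoregistrationValidation:
    """Across-day correlation of mean peak amplitude and PNR for matched cells."""
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    n_pairs = matching.pairs.shape[0]
    stats_i = population_peak_stats(
        session_i.traces, session_i.sample_rate_hz, config.peak_prominence_sd
    )
    stats_j = population_peak_stats(
        session_j.traces, session_j.sample_rate_hz, config.peak_prominence_sd
    )
    amp_i = np.array([stats_i[i].mean_peak_amplitude for i, _ in matching.pairs])
    amp_j = np.array([stats_j[j].mean_peak_amplitude for _, j in matching.pairs])
    pnr_i = np.array([stats_i[i].peak_to_noise_ratio for i, _ in matching.pairs])
    pnr_j = np.array([stats_j[j].peak_to_noise_ratio for _, j in matching.pairs])

    def corr(a, b):
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return np.nan, np.nan
        return (
            float(stats.spearmanr(a[ok], b[ok]).statistic),
            _shuffle_chance(a[ok], b[ok], rng, n_iter, config.percentile),
        )

    amp_r, amp_chance = corr(amp_i, amp_j)
    pnr_r, pnr_chance = corr(pnr_i, pnr_j)
    return CoregistrationValidation(
        amplitude_r=amp_r,
        amplitude_chance=amp_chance,
        pnr_r=pnr_r,
        pnr_chance=pnr_chance,
        n_pairs=n_pairs,
        low_power=n_pairs < 10,
    )


@dataclass
class StabilityReport:
    map_r_across: np.ndarray      # per matched day-i place cell
    map_r_within: np.ndarray      # within-day half-half comparison
    mi_r: float
    mi_chance: float
    speed_r_r: float
    speed_r_chance: float
    n_matched: int
    n_matched_place: int


def across_day_stability(
    session_i: Session,
    session_j: Session,
    matching: Matching,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    min_place_cells: int = 5,
    n_iter: int = 1000,
) -> StabilityReport:
    """Across-day stability of spatial maps, MI and speed tuning."""
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    beh_i = analyze_behavior(session_i, config)
    beh_j = analyze_behavior(session_j, config)
    place_i = classify_place_cells(session_i, config, beh_i, with_fields=False)
    place_j = classify_place_cells(session_j, config, beh_j, with_fields=False)
    speed_i = classify_speed_cells(session_i, config, beh_i)
    speed_j = classify_speed_cells(session_j, config, beh_j)

    def profile(session, beh, cell, sl=None):
        if sl is not None:
            sub = session.subsession(sl)
            beh = analyze_behavior(sub, config)
            trace = sub.traces[cell]
            session = sub
        else:
            trace = session.traces[cell]
        amap = compute_activity_map(
            trace, beh, session.meta.track_length_cm, session.meta.track_width_cm,
            config, smooth=True,
        )
        return flatten_map(amap)

    place_pairs = [
        (i, j) for i, j in matching.pairs if place_i[i].is_place_cell
    ]
    map_r_across = np.array(
        [
            rate_map_correlation(profile(session_i, beh_i, i), profile(session_j, beh_j, j))
            for i, j in place_pairs
        ]
    )
    # within-day control: first vs second half of day i for the same cells
    sl1, sl2 = session_i.half_slices()
    map_r_within = np.array(
        [
            rate_map_correlation(
                profile(session_i, beh_i, i, sl1), profile(session_i, beh_i, i, sl2)
            )
            for i, _ in place_pairs
        ]
    )
    mi_i = np.array([place_i[i].mi for i, _ in matching.pairs])
    mi_j = np.array([place_j[j].mi for _, j in matching.pairs])
    sr_i = np.array([speed_i[i].spearman_r for i, _ in matching.pairs])
    sr_j = np.array([speed_j[j].spearman_r for _, j in matching.pairs])

    def corr(a, b):
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return np.nan, np.nan
        return (
            float(stats.spearmanr(a[ok], b[ok]).statistic),
            _shuffle_chance(a[ok], b[ok], rng, n_iter, config.percentile),
        )

    mi_r, mi_chance = corr(mi_i, mi_j)
    sr_r, sr_chance = corr(sr_i, sr_j)
    return StabilityReport(
        map_r_across=map_r_across,
        map_r_within=map_r_within,
        mi_r=mi_r,
        mi_chance=mi_chance,
        speed_r_r=sr_r,
        speed_r_chance=sr_chance,
        n_matched=matching.pairs.shape[0],
        n_matched_place=len(place_pairs),
    )
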
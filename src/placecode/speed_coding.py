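"""Speed-cell classification and GLM speed decoding.

Speed tuning is measured on position-regressed activity: a Gaussian-family,
identity-link model of df/F on one-hot 3.5 cm position bins is fit per cell
and its prediction subtracted, so arbitrary place tuning cannot masquerade
as speed tuning.  A cell is speed-positive (negative) when the Spearman
correlation of its residual trace with speed exceeds the 95th (falls below
the 5th) percentile of a null built from fixed circular shifts of the speed
vector.

Decoding predicts instantaneous speed at the neural sample rate from the
position-regressed population, fit on alternating 60 s blocks (10 s guards;
odd blocks train, even blocks test) and scored as the Spearman correlation
of actual and predicted speed on the concatenated test samples, averaged
over 100 random cell subsets of fixed size.  The chance level repeats the
identical block/fit/subsample pipeline on circularly shifted speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import BehaviorSeries, analyze_behavior
from .io_core import AnalysisConfig, Session
from .nulls import cyclic_offsets, lower_threshold, upper_threshold
from .spatial_coding import bin_position, n_position_bins


def regress_out_position(
    trace: np.ndarray,
    x_position: np.ndarray,
    track_length_cm: float,
    bin_cm: float = 3.5,
) -> np.ndarray:
    """Residual df/F after removing the one-hot position-bin fit.

    With one-hot predictors and an identity link the fitted value in each
    bin is simply the bin mean, so the regression is exact and fast.
    """
    trace = np.asarray(trace, dtype=float)
    xb = bin_position(x_position, track_length_cm, bin_cm)
    if np.unique(xb).size < 2:
        warnings.warn("constant position; returning mean-centered trace")
        return trace - trace.mean()
    nx = n_position_bins(track_length_cm, bin_cm)
    sums = np.bincount(xb, weights=trace, minlength=nx)
    counts = np.bincount(xb, minlength=nx)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return trace - means[xb]


@dataclass
class SpeedCellResult:
    spearman_r: float
    null_r: np.ndarray
    upper: float
    lower: float
    speed_class: str  # "positive" | "negative" | "none"


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def classify_speed_cells(
    session: Session,
    config: AnalysisConfig | None = None,
    behavior: BehaviorSeries | None = None,
) -> list[SpeedCellResult]:
    """Two-sided speed-cell classification for every cell of a session.

    The null reuses the ranks: circularly shifting the speed vector shifts
    its rank vector identically, so all null correlations reduce to one
    matrix product of centered rank vectors.
    """
    config = config or AnalysisConfig()
    behavior = behavior or analyze_behavior(session, config)
    keep = session.kept_samples()
    speed = behavior.speed[keep]
    x = behavior.x[keep]
    L = session.meta.track_length_cm
    T = speed.size
    offsets = cyclic_offsets(T, config.n_shuffles_speed)
    s_rank = _rank(speed)
    s_rank = s_rank - s_rank.mean()
    s_norm = np.linalg.norm(s_rank)
    shifted = np.empty((offsets.size, T))
    for i, off in enumerate(offsets):
        shifted[i] = np.roll(s_rank, off)
    results: list[SpeedCellResult] = []
    for trace in session.traces:
        resid = regress_out_position(trace[keep], x, L, config.spatial_bin_cm)
        if np.allclose(resid, resid[0]):
            results.append(SpeedCellResult(np.nan, np.empty(0), np.nan, np.nan, "none"))
            continue
        r_rank = _rank(resid)
        r_rank = r_rank - r_rank.mean()
        denom = np.linalg.norm(r_rank) * s_norm
        r_obs = float(r_rank @ s_rank / denom)
        null = shifted @ r_rank / denom
        hi = upper_threshold(null, config.percentile)
        lo = lower_threshold(null, 100.0 - config.percentile)
        if r_obs > hi:
            cls = "positive"
        elif r_obs < lo:
            cls = "negative"
        else:
            cls = "none"
        results.append(SpeedCellResult(r_obs, null, hi, lo, cls))
    return results


def split_consistency(
    session: Session,
    split: str = "left_right",
    config: AnalysisConfig | None = None,
    behavior: BehaviorSeries | None = None,
    min_samples: int = 100,
) -> float:
    """Across-cell consistency of speed tuning between two sample partitions.

    Per cell, the Spearman correlation of df/F and speed is computed within
    each partition (left/right halves of the track, or first/second halves
    of the session); the two per-cell r vectors are then Spearman-correlated
    across cells.
    """
    config = config or AnalysisConfig()
    behavior = behavior or analyze_behavior(session, config)
    keep = session.kept_samples()
    speed = behavior.speed[keep]
    if split == "left_right":
        part1 = behavior.x[keep] < session.meta.track_length_cm / 2.0
    elif split == "half_half":
        part1 = np.arange(speed.size) < speed.size // 2
    else:
        raise ValueError(f"unknown split {split!r}")
    part2 = ~part1
    for name, part in (("first", part1), ("second", part2)):
        if part.sum() < min_samples:
            raise ValueError(f"{name} partition of split {split!r} has too few samples")
    traces = session.traces[:, keep]
    r1 = np.array([stats.spearmanr(t[part1], speed[part1]).statistic for t in traces])
    r2 = np.array([stats.spearmanr(t[part2], speed[part2]).statistic for t in traces])
    return float(stats.spearmanr(r1, r2).statistic)


# ---------------------------------------------------------------------------
# decoding


@dataclass
class DecodingResult:
    mean_r: float
    iteration_r: np.ndarray
    chance_threshold: float
    null_r: np.ndarray
    n_cells_used: int
    n_train: int
    n_test: int


def alternating_blocks(
    n_samples: int, sample_rate_hz: float, block_s: float = 60.0, guard_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices of alternating train/test blocks with guard gaps."""
    block = int(round(block_s * sample_rate_hz))
    guard = int(round(guard_s * sample_rate_hz))
    train, test = [], []
    start, i = 0, 0
    while start + block <= n_samples:
        idx = np.arange(start, start + block)
        (train if i % 2 == 0 else test).append(idx)
        start += block + guard
        i += 1
    if not train or not test:
        raise ValueError("session too short for alternating blocks")
    return np.concatenate(train), np.concatenate(test)


def _fit_predict(X_train, y_train, X_test) -> np.ndarray:
    """Gaussian identity-link linear model; ridge jitter if singular."""
    A = X_train.T @ X_train
    b = X_train.T @ y_train
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        alpha = 1e-8 * np.trace(A) / A.shape[0]
        w = np.linalg.solve(A + alpha * np.eye(A.shape[0]), b)
    return X_test @ w


def decode_speed(
    session: Session,
    n_subsample: int,
    config: AnalysisConfig | None = None,
    behavior: BehaviorSeries | None = None,
    rng: np.random.Generator | None = None,
    predictors: np.ndarray | None = None,
) -> DecodingResult:
    """Decode instantaneous speed from the position-regressed population.

    ``predictors`` overrides the default position-regressed traces (used by
    oracle and null experiments).
    """
    config = config or AnalysisConfig()
    behavior = behavior or analyze_behavior(session, config)
    rng = rng or np.random.default_rng(config.rng_seed)
    keep = session.kept_samples()
    speed = behavior.speed[keep]
    x = behavior.x[keep]
    L = session.meta.track_length_cm
    if predictors is None:
        predictors = np.stack(
            [
                regress_out_position(t[keep], x, L, config.spatial_bin_cm)
                for t in session.traces
            ]
        )
    n_cells = predictors.shape[0]
    if n_subsample > n_cells:
        raise ValueError(f"n_subsample={n_subsample} exceeds {n_cells} cells")
    train, test = alternating_blocks(
        speed.size, session.sample_rate_hz, config.decode_block_s, config.decode_guard_s
    )

    def score(speed_vec: np.ndarray, subset: np.ndarray) -> float:
        X = predictors[subset].T
        X = np.column_stack([np.ones(X.shape[0]), X])
        pred = _fit_predict(X[train], speed_vec[train], X[test])
        return float(stats.spearmanr(speed_vec[test], pred).statistic)

    iter_r = np.array(
        [
            score(speed, rng.choice(n_cells, size=n_subsample, replace=False))
            for _ in range(config.decode_n_iter)
        ]
    )
    offsets = cyclic_offsets(speed.size, config.n_shuffles_speed)
    null_r = np.array(
        [
            score(np.roll(speed, off), rng.choice(n_cells, size=n_subsample, replace=False))
            for off in offsets
        ]
    )
    return DecodingResult(
        mean_r=float(iter_r.mean()),
        iteration_r=iter_r,
        chance_threshold=upper_threshold(null_r, config.percentile),
        null_r=null_r,
        n_cells_used=n_subsample,
        n_train=train.size,
        n_test=test.size,
    )


def path_length_exclusions(path_lengths_cm: np.ndarray) -> np.ndarray:
    """Flag sessions whose path length falls 1 SD below the cohort mean."""
    p = np.asarray(path_lengths_cm, dtype=float)
    return p < p.mean() - p.std()
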
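"""Ground-truth synthetic sessions: trajectories, tuned populations, df/F.

The generator emulates the statistical structure the analyses assume for a
freely exploring mouse on a 1-D track:

* a bout-structured random walk (run/pause alternation) so both sub- and
  supra-threshold (3 cm/s) epochs exist and occupancy covers the track;
* two cell-type archetypes — CAMK2A-like (sparser, faster transients) and
  VGAT-like (higher event rate, wider transients);
* 1-D Gaussian place fields, linear speed gains on the event-rate scale,
  mid-session rotation/rescaling manipulations, across-day turnover with
  jittered footprints, and injected synchronous population events.

Events are Bernoulli per sample at rate x dt (dt = 1/7.5 s), convolved with
a single-exponential transient and corrupted with Gaussian noise, so every
rendered trace is exactly bookkept by its latent event raster.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_core import Session, SessionMeta

ARCHETYPES = {
    # baseline event rate (events/s), transient decay tau (s).  The decay
    # constants keep the two archetypes' *detected* peak statistics ordered
    # (rate and width both higher for VGAT-like) under the 2-SD prominence
    # rule; very long decays at the VGAT rate would merge transients and
    # invert the detected-rate ordering.
    "CAMK2A": (0.11, 0.9),
    "VGAT": (0.17, 1.4),
}

RESCALE_LENGTHS = {"med_med": 70.0, "med_short": 35.0, "med_long": 105.0}


@dataclass
class SimulationConfig:
    """Generator parameters; defaults define the reference study conditions."""

    track_length_cm: float = 70.0
    track_width_cm: float = 9.0
    duration_s: float = 1200.0
    sample_rate_hz: float = 7.5
    n_cells: int = 100
    cell_type: str = "CAMK2A"
    baseline_rate_hz: float | None = None       # archetype default if None
    transient_decay_s: float | None = None      # archetype default if None
    fraction_place_cells: float = 0.5
    field_width_cm_mean: float = 14.0
    field_width_cm_sd: float = 4.0
    field_width_cm_min: float = 6.0
    place_peak_rate_hz: float = 0.8
    place_offfield_rate_hz: float = 0.02
    fraction_speed_pos: float = 0.15
    fraction_speed_neg: float = 0.15
    speed_slope_per_cm_s: float = 0.10
    speed_ref_cm_s: float = 8.0
    p_rotate: float = 0.0
    p_stable: float = 1.0
    rescale_mode: str = "scale_with_track"      # or "fixed"
    p_survive: float = 0.5
    footprint_jitter_px: float = 1.0
    amplitude_persistence: float = 1.0
    p_keep_place_tuning: float = 1.0
    popevent_n: int = 0
    popevent_participation: float = 0.6
    popevent_speed_regime: str = "low"          # or "high"
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.3
    event_amp_jitter: float = 0.15
    noise_sd: float = 0.06
    footprint_grid_px: int = 128
    footprint_sigma_px: float = 2.5
    # trajectory bout structure
    run_speed_cm_s: tuple[float, float] = (5.0, 25.0)
    pause_speed_cm_s: tuple[float, float] = (0.0, 1.5)
    run_duration_s: tuple[float, float] = (1.5, 6.0)
    pause_duration_s: tuple[float, float] = (0.5, 2.5)
    y_jitter_cm: float = 0.3
    pose_noise_cm: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type not in ARCHETYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        base, tau = ARCHETYPES[self.cell_type]
        if self.baseline_rate_hz is None:
            self.baseline_rate_hz = base
        if self.transient_decay_s is None:
            self.transient_decay_s = tau
        for name in ("fraction_place_cells", "fraction_speed_pos", "fraction_speed_neg",
                     "p_rotate", "p_stable", "p_survive", "popevent_participation",
                     "p_keep_place_tuning"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_rotate + self.p_stable > 1.0 + 1e-12:
            raise ValueError("p_rotate + p_stable must not exceed 1")
        if self.baseline_rate_hz <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.rescale_mode not in ("scale_with_track", "fixed"):
            raise ValueError("rescale_mode must be 'scale_with_track' or 'fixed'")
        if self.popevent_speed_regime not in ("low", "high"):
            raise ValueError("popevent_speed_regime must be 'low' or 'high'")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz


@dataclass
class GroundTruth:
    """Per-cell generative parameters; the recovery target for the analyses."""

    ids: np.ndarray
    is_place: np.ndarray
    field_center_cm: np.ndarray     # NaN for non-place cells
    field_width_cm: np.ndarray
    speed_class: np.ndarray         # +1, -1 or 0
    speed_slope: np.ndarray
    remap_label: np.ndarray         # "rotate" | "stable" | "random" | ""
    amplitude: np.ndarray
    popevent_participant: np.ndarray
    footprint_center_px: np.ndarray | None = None
    popevent_samples: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_cells(self) -> int:
        return self.ids.size

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            **{
                f.name: (getattr(self, f.name).copy()
                         if isinstance(getattr(self, f.name), np.ndarray)
                         else getattr(self, f.name))
                for f in dataclasses.fields(self)
            }
        )


@dataclass
class Trajectory:
    x_cm: np.ndarray
    y_cm: np.ndarray
    speed_cm_s: np.ndarray
    sample_rate_hz: float
    track_length_cm: float
    track_width_cm: float


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_trajectory(config: SimulationConfig, seed=None) -> Trajectory:
    """Bout-structured 1-D exploration with reflective walls."""
    if config.track_length_cm <= 2 * 3.5:
        raise ValueError("track shorter than two spatial bins")
    rng = _rng(config.rng_seed if seed is None else seed)
    n = config.n_samples
    dt = config.dt
    L, W = config.track_length_cm, config.track_width_cm
    x = np.empty(n)
    y = np.empty(n)
    x[0] = L / 2.0
    y[0] = W / 2.0
    direction = 1.0
    t = 0
    running = True
    while t < n - 1:
        if running:
            dur = rng.uniform(*config.run_duration_s)
            speed = rng.uniform(*config.run_speed_cm_s)
        else:
            dur = rng.uniform(*config.pause_duration_s)
            speed = rng.uniform(*config.pause_speed_cm_s)
        steps = max(int(round(dur / dt)), 1)
        for _ in range(steps):
            if t >= n - 1:
                break
            v = speed * (1.0 + 0.15 * rng.standard_normal())
            nx_pos = x[t] + direction * max(v, 0.0) * dt
            if nx_pos < 0.5:
                nx_pos = 1.0 - nx_pos
                direction = 1.0
            elif nx_pos > L - 0.5:
                nx_pos = 2 * (L - 0.5) - nx_pos
                direction = -1.0
            x[t + 1] = np.clip(nx_pos, 0.0, L)
            y[t + 1] = np.clip(
                y[t] + config.y_jitter_cm * rng.standard_normal(), 0.0, W
            )
            t += 1
        if running and rng.random() < 0.35:
            direction = -direction
        running = not running
    dx = np.diff(x)
    dy = np.diff(y)
    speed_true = np.empty(n)
    speed_true[1:] = np.hypot(dx, dy) / dt
    speed_true[0] = speed_true[1] if n > 1 else 0.0
    return Trajectory(x, y, speed_true, config.sample_rate_hz, L, W)


def _exact_choice(rng, n, k, exclude=None) -> np.ndarray:
    pool = np.arange(n)
    if exclude is not None:
        pool = pool[~np.isin(pool, exclude)]
    k = min(k, pool.size)
    return rng.choice(pool, size=k, replace=False)


def simulate_population(config: SimulationConfig, seed=None) -> GroundTruth:
    """Draw per-cell tuning by the configured fractions (exact counts)."""
    rng = _rng(config.rng_seed if seed is None else seed)
    n = config.n_cells
    L = config.track_length_cm
    is_place = np.zeros(n, dtype=bool)
    place_idx = _exact_choice(rng, n, int(round(config.fraction_place_cells * n)))
    is_place[place_idx] = True
    centers = np.full(n, np.nan)
    widths = np.full(n, np.nan)
    centers[place_idx] = rng.uniform(0.05 * L, 0.95 * L, size=place_idx.size)
    w = rng.normal(config.field_width_cm_mean, config.field_width_cm_sd, size=place_idx.size)
    widths[place_idx] = np.maximum(w, config.field_width_cm_min)
    speed_class = np.zeros(n, dtype=int)
    pos_idx = _exact_choice(rng, n, int(round(config.fraction_speed_pos * n)))
    speed_class[pos_idx] = 1
    neg_idx = _exact_choice(rng, n, int(round(config.fraction_speed_neg * n)), exclude=pos_idx)
    speed_class[neg_idx] = -1
    slope = speed_class * config.speed_slope_per_cm_s
    remap = np.array([""] * n, dtype=object)
    n_pl = place_idx.size
    n_rot = int(round(config.p_rotate * n_pl))
    n_sta = int(round(config.p_stable * n_pl))
    n_sta = min(n_sta, n_pl - n_rot)
    perm = rng.permutation(place_idx)
    remap[perm[:n_rot]] = "rotate"
    remap[perm[n_rot : n_rot + n_sta]] = "stable"
    remap[perm[n_rot + n_sta :]] = "random"
    amp = config.amplitude_mean * np.exp(
        config.amplitude_cv * rng.standard_normal(n) - 0.5 * config.amplitude_cv**2
    )
    part = np.zeros(n, dtype=bool)
    part_idx = _exact_choice(rng, n, int(round(config.popevent_participation * n)))
    part[part_idx] = True
    return GroundTruth(
        ids=np.arange(n),
        is_place=is_place,
        field_center_cm=centers,
        field_width_cm=widths,
        speed_class=speed_class,
        speed_slope=slope.astype(float),
        remap_label=remap,
        amplitude=amp,
        popevent_participant=part,
    )


# ---------------------------------------------------------------------------
# rendering


def _cell_rates(gt: GroundTruth, traj: Trajectory, config: SimulationConfig) -> np.ndarray:
    """Per-cell instantaneous event rate (events/s), cells x samples."""
    n, T = gt.n_cells, traj.x_cm.size
    rates = np.empty((n, T))
    v = traj.speed_cm_s
    for i in range(n):
        if gt.is_place[i]:
            sigma = gt.field_width_cm[i] / 4.0
            gain = np.exp(-0.5 * ((traj.x_cm - gt.field_center_cm[i]) / sigma) ** 2)
            rate = config.place_offfield_rate_hz + (
                config.place_peak_rate_hz - config.place_offfield_rate_hz
            ) * gain
        else:
            rate = np.full(T, config.baseline_rate_hz)
        if gt.speed_class[i] != 0:
            rate = rate * (1.0 + gt.speed_slope[i] * (v - config.speed_ref_cm_s))
        rates[i] = np.maximum(rate, 0.0)
    return rates


def _transient_kernel(tau_s: float, sample_rate_hz: float) -> np.ndarray:
    n_k = max(int(np.ceil(6.0 * tau_s * sample_rate_hz)), 2)
    t = np.arange(n_k) / sample_rate_hz
    return np.exp(-t / tau_s)


def _pose_from_trajectory(traj: Trajectory, config: SimulationConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Nose/ear/tailbase table; the tailbase is the simulated point."""
    T = traj.x_cm.size
    dx = np.gradient(traj.x_cm)
    dy = np.gradient(traj.y_cm)
    norm = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        hx = np.where(norm > 1e-9, dx / norm, 1.0)
        hy = np.where(norm > 1e-9, dy / norm, 0.0)
    noise = lambda: config.pose_noise_cm * rng.standard_normal(T)
    L, W = traj.track_length_cm, traj.track_width_cm
    pose = np.column_stack(
        [
            np.clip(traj.x_cm + 6.0 * hx + noise(), 0, L),   # nose
            np.clip(traj.y_cm + 6.0 * hy + noise(), 0, W),
            np.clip(traj.x_cm + 3.0 * hx + noise(), 0, L),   # ear
            np.clip(traj.y_cm + 3.0 * hy + noise(), 0, W),
            traj.x_cm + noise(),                              # tailbase
            traj.y_cm + noise(),
        ]
    )
    return pose


def _select_event_samples(traj: Trajectory, config: SimulationConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Target samples for injected population events in one speed regime."""
    v = traj.speed_cm_s
    if config.popevent_speed_regime == "low":
        pool = np.flatnonzero(v < 3.0)
    else:
        pool = np.flatnonzero(v > np.percentile(v, 60))
    if pool.size < config.popevent_n:
        pool = np.argsort(v if config.popevent_speed_regime == "low" else -v)[
            : max(config.popevent_n * 2, 1)
        ]
    chosen = rng.choice(pool, size=min(config.popevent_n, pool.size), replace=False)
    chosen.sort()
    # keep events at least 3 samples apart so detections stay separable
    keep = [int(chosen[0])] if chosen.size else []
    for s in chosen[1:]:
        if s - keep[-1] >= 3:
            keep.append(int(s))
    return np.asarray(keep, dtype=int)


@dataclass
class RenderResult:
    session: Session
    events: np.ndarray          # latent binary raster, cells x samples
    clipped_rate_samples: int   # rate*dt values clipped into [0, 1]


def render_session(
    ground_truth: GroundTruth,
    trajectory: Trajectory,
    config: SimulationConfig,
    seed=None,
    meta: SessionMeta | None = None,
) -> RenderResult:
    """Render df/F traces from tuning + trajectory with exact bookkeeping."""
    rng = _rng(config.rng_seed if seed is None else seed)
    gt = ground_truth
    T = trajectory.x_cm.size
    rates = _cell_rates(gt, trajectory, config)
    p = rates * config.dt
    clipped = int((p > 1.0).sum())
    p = np.clip(p, 0.0, 1.0)
    events = rng.random(p.shape) < p
    if config.popevent_n > 0 and gt.popevent_samples.size == 0:
        gt.popevent_samples = _select_event_samples(trajectory, config, rng)
    if gt.popevent_samples.size:
        events[np.ix_(gt.popevent_participant, gt.popevent_samples)] = True
    kernel = _transient_kernel(config.transient_decay_s, config.sample_rate_hz)
    traces = np.empty((gt.n_cells, T))
    for i in range(gt.n_cells):
        amps = np.zeros(T)
        ev = np.flatnonzero(events[i])
        if ev.size:
            jitter = 1.0 + config.event_amp_jitter * rng.standard_normal(ev.size)
            amps[ev] = gt.amplitude[i] * np.maximum(jitter, 0.1)
        traces[i] = np.convolve(amps, kernel)[:T]
    traces += config.noise_sd * rng.standard_normal(traces.shape)
    pose = _pose_from_trajectory(trajectory, config, rng)
    meta = meta or SessionMeta(
        track_length_cm=trajectory.track_length_cm,
        track_width_cm=trajectory.track_width_cm,
        cell_type=config.cell_type,
    )
    footprints = None
    if gt.footprint_center_px is not None:
        footprints = render_footprints(
            gt.footprint_center_px, config.footprint_grid_px, config.footprint_sigma_px
        )
    session = Session(
        traces=traces,
        pose=pose,
        sample_rate_hz=config.sample_rate_hz,
        footprints=footprints,
        meta=meta,
    )
    return RenderResult(session=session, events=events, clipped_rate_samples=clipped)


# ---------------------------------------------------------------------------
# manipulations


def transform_ground_truth(
    gt: GroundTruth, config: SimulationConfig, kind: str, seed=None
) -> GroundTruth:
    """Half-2 tuning under a manipulation, per each cell's remap label."""
    rng = _rng(config.rng_seed if seed is None else seed)
    L1 = config.track_length_cm
    gt2 = gt.copy()
    if kind in ("rotate0", "rotate180"):
        for i in np.flatnonzero(gt.is_place):
            lab = gt.remap_label[i]
            if lab == "rotate":
                gt2.field_center_cm[i] = L1 - gt.field_center_cm[i]
            elif lab == "random":
                gt2.field_center_cm[i] = rng.uniform(0.05 * L1, 0.95 * L1)
    elif kind in RESCALE_LENGTHS:
        L2 = RESCALE_LENGTHS[kind]
        ratio = L2 / 70.0
        if config.rescale_mode == "scale_with_track":
            gt2.field_center_cm[gt.is_place] *= ratio
            gt2.field_width_cm[gt.is_place] *= ratio
        else:
            # fixed fields may fall off a shortened track; clip centers inside
            gt2.field_center_cm[gt.is_place] = np.clip(
                gt2.field_center_cm[gt.is_place], 0.05 * L2, 0.95 * L2
            )
        rand = gt.is_place & (gt.remap_label == "random")
        gt2.field_center_cm[rand] = rng.uniform(0.05 * L2, 0.95 * L2, size=rand.sum())
    else:
        raise ValueError(f"unknown manipulation kind {kind!r}")
    return gt2


def simulate_manipulation_pair(
    ground_truth: GroundTruth, config: SimulationConfig, kind: str, seed=None
) -> tuple[Session, Session, GroundTruth]:
    """Render both halves of a rotation/rescaling session."""
    rng = _rng(config.rng_seed if seed is None else seed)
    gt2 = transform_ground_truth(ground_truth, config, kind, rng)
    half_cfg = config.replace(duration_s=config.duration_s / 2.0)
    L2 = RESCALE_LENGTHS.get(kind, config.track_length_cm)
    half2_cfg = half_cfg.replace(track_length_cm=L2)
    traj1 = simulate_trajectory(half_cfg, rng)
    traj2 = simulate_trajectory(half2_cfg, rng)
    meta1 = SessionMeta(
        track_length_cm=config.track_length_cm,
        track_length_half2_cm=L2,
        track_width_cm=config.track_width_cm,
        manipulation=kind,
        cell_type=config.cell_type,
    )
    meta2 = SessionMeta(
        track_length_cm=L2,
        track_length_half2_cm=L2,
        track_width_cm=config.track_width_cm,
        manipulation=kind,
        cell_type=config.cell_type,
    )
    r1 = render_session(ground_truth, traj1, half_cfg, rng, meta=meta1)
    r2 = render_session(gt2, traj2, half2_cfg, rng, meta=meta2)
    return r1.session, r2.session, gt2


def combine_halves(half1: Session, half2: Session, gap_s: float = 20.0) -> Session:
    """Stitch two halves with an excised junction interval between them."""
    rate = half1.sample_rate_hz
    gap = int(round(gap_s * rate))
    n1 = half1.n_samples
    traces = np.concatenate(
        [half1.traces, np.zeros((half1.n_cells, gap)), half2.traces], axis=1
    )
    hold = np.repeat(half1.pose[-1][None, :], gap, axis=0)
    pose = np.concatenate([half1.pose, hold, half2.pose], axis=0)
    meta = SessionMeta.from_dict(half1.meta.to_dict())
    meta.track_length_half2_cm = half2.meta.track_length_cm
    return Session(
        traces=traces,
        pose=pose,
        sample_rate_hz=rate,
        footprints=half1.footprints,
        meta=meta,
        removed_interval=(n1, n1 + gap),
    )


# ---------------------------------------------------------------------------
# multiday


def _place_footprint_centers(
    n: int, grid: int, rng: np.random.Generator,
    existing: np.ndarray | None = None, min_dist: float = 5.0,
) -> np.ndarray:
    """Rejection-sample footprint centers with a minimum separation."""
    taken = (
        np.empty((0, 2)) if existing is None else np.asarray(existing, float).reshape(-1, 2)
    )
    out = np.empty((n, 2))
    margin = 6.0
    for i in range(n):
        c = rng.uniform(margin, grid - margin, size=2)
        for _try in range(200):
            if taken.size == 0 or np.min(np.hypot(*(taken - c).T)) >= min_dist:
                break
            c = rng.uniform(margin, grid - margin, size=2)
        taken = np.vstack([taken, c])
        out[i] = c
    return out


def render_footprints(centers_px: np.ndarray, grid: int, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:grid, 0:grid]
    fps = np.empty((centers_px.shape[0], grid, grid), dtype=np.float32)
    for i, (cy, cx) in enumerate(centers_px):
        fps[i] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    return fps


@dataclass
class MultidayResult:
    sessions: list[Session]
    ground_truths: list[GroundTruth]
    events: list[np.ndarray]
    survived: list[np.ndarray]   # bool per day-pair over previous day's cells


def simulate_multiday(config: SimulationConfig, n_days: int, seed=None) -> MultidayResult:
    """Sessions across days with Bernoulli survival and footprint jitter."""
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = _rng(config.rng_seed if seed is None else seed)
    gt = simulate_population(config, rng)
    gt.footprint_center_px = _place_footprint_centers(
        gt.n_cells, config.footprint_grid_px, rng
    )
    next_id = gt.n_cells
    sessions, gts, events, survived = [], [], [], []
    log_mu = np.log(config.amplitude_mean) - 0.5 * config.amplitude_cv**2
    for day in range(n_days):
        traj = simulate_trajectory(config, rng)
        meta = SessionMeta(
            track_length_cm=config.track_length_cm,
            track_width_cm=config.track_width_cm,
            cell_type=config.cell_type,
            day=day,
            session_id=f"day{day}",
        )
        rr = render_session(gt, traj, config, rng, meta=meta)
        sessions.append(rr.session)
        gts.append(gt)
        events.append(rr.events)
        if day == n_days - 1:
            break
        surv = rng.random(gt.n_cells) < config.p_survive
        survived.append(surv)
        nxt = gt.copy()
        rho = config.amplitude_persistence
        # survivors: persist amplitude on the log scale with correlation rho
        z1 = (np.log(gt.amplitude) - log_mu) / max(config.amplitude_cv, 1e-12)
        z2 = rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(gt.n_cells)
        nxt.amplitude = np.exp(log_mu + config.amplitude_cv * z2)
        jitter_angle = rng.uniform(0, 2 * np.pi, gt.n_cells)
        jitter_rad = config.footprint_jitter_px * np.sqrt(rng.random(gt.n_cells))
        nxt.footprint_center_px = gt.footprint_center_px + np.column_stack(
            [jitter_rad * np.cos(jitter_angle), jitter_rad * np.sin(jitter_angle)]
        )
        redraw_place = gt.is_place & (rng.random(gt.n_cells) >= config.p_keep_place_tuning)
        L = config.track_length_cm
        nxt.field_center_cm[redraw_place] = rng.uniform(
            0.05 * L, 0.95 * L, size=redraw_place.sum()
        )
        # non-survivors are replaced by new cells at new locations
        dead = np.flatnonzero(~surv)
        if dead.size:
            fresh = simulate_population(config.replace(n_cells=dead.size), rng)
            # keep newcomers away from every earlier center, surviving or
            # not: a new cell at a dead cell's location would make identity
            # unrecoverable in principle
            occupied = np.vstack([nxt.footprint_center_px[surv], gt.footprint_center_px])
            new_centers = _place_footprint_centers(
                dead.size, config.footprint_grid_px, rng, existing=occupied,
            )
            nxt.ids[dead] = next_id + np.arange(dead.size)
            next_id += dead.size
            nxt.is_place[dead] = fresh.is_place
            nxt.field_center_cm[dead] = fresh.field_center_cm
            nxt.field_width_cm[dead] = fresh.field_width_cm
            nxt.speed_class[dead] = fresh.speed_class
            nxt.speed_slope[dead] = fresh.speed_slope
            nxt.remap_label[dead] = fresh.remap_label
            nxt.amplitude[dead] = fresh.amplitude
            nxt.footprint_center_px[dead] = new_centers
        gt = nxt
    return MultidayResult(sessions, gts, events, survived)
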
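"""Recovery and calibration experiments on the synthetic generator.

Each function runs one self-contained experiment — classifier calibration on
untuned populations, parameter recovery on tuned ones, detection of injected
population events, cross-day matching accuracy — and returns the measured
quantity.  The experiments are shared by the test suite and the acceptance
script; problem sizes are arguments so callers choose their own budget.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .behavior import analyze_behavior
from .io_core import AnalysisConfig, Session
from .multiday import (
    across_day_stability,
    coregistration_validation,
    match_cells,
    turnover_fraction,
)
from .pipeline import run_pipeline
from .population_events import detect_population_events, event_raster
from .remapping import analyze_half_pair
from .spatial_coding import (
    classify_place_cells,
    compute_activity_map,
    mutual_information_from_joint,
)
from .speed_coding import classify_speed_cells, decode_speed
from .synthetic_data import (
    SimulationConfig,
    combine_halves,
    render_session,
    simulate_manipulation_pair,
    simulate_multiday,
    simulate_population,
    simulate_trajectory,
)


def _brute_force_mi(joint: np.ndarray) -> float:
    """Literal double-sum over the joint table, in bits."""
    p = np.asarray(joint, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


def mi_oracle_gap(n_tables: int = 20, seed: int = 0) -> float:
    """Max |MI - brute force| over random joint tables."""
    rng = np.random.default_rng(seed)
    gap = 0.0
    for _ in range(n_tables):
        counts = rng.integers(0, 30, size=(4, 6)).astype(float)
        counts[0, 0] += 1.0
        joint = counts / counts.sum()
        gap = max(gap, abs(mutual_information_from_joint(joint) - _brute_force_mi(joint)))
    return gap


def _noise_session(cfg: SimulationConfig, n_cells: int, seed: int) -> Session:
    """White-noise traces paired with a real trajectory (untuned population)."""
    rng = np.random.default_rng(seed)
    traj = simulate_trajectory(cfg, rng)
    gt = simulate_population(
        cfg.replace(n_cells=1, fraction_place_cells=0.0,
                    fraction_speed_pos=0.0, fraction_speed_neg=0.0),
        rng,
    )
    rr = render_session(gt, traj, cfg.replace(n_cells=1), rng)
    sess = rr.session
    return Session(
        traces=rng.standard_normal((n_cells, sess.n_samples)),
        pose=sess.pose,
        sample_rate_hz=sess.sample_rate_hz,
        meta=sess.meta,
    )


def place_null_fp_rate(
    n_cells: int = 200, n_seeds: int = 20, duration_s: float = 600.0, seed: int = 0
) -> float:
    """Fraction of untuned cells classified as place cells."""
    fp = 0
    total = 0
    cfg = SimulationConfig(duration_s=duration_s)
    for k in range(n_seeds):
        sess = _noise_session(cfg, n_cells, seed + 7919 * k)
        res = classify_place_cells(sess, with_fields=False)
        fp += sum(r.is_place_cell for r in res)
        total += len(res)
    return fp / total


def place_recovery(
    n_seeds: int = 5, n_cells: int = 100, duration_s: float = 600.0, seed: int = 0
) -> tuple[float, float]:
    """(sensitivity on true place cells, fraction of centers within one bin)."""
    detected = 0
    n_place = 0
    hits = 0
    n_centers = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(duration_s=duration_s, n_cells=n_cells, rng_seed=seed + k)
        gt = simulate_population(cfg, seed + k)
        traj = simulate_trajectory(cfg, seed + k + 1000)
        sess = render_session(gt, traj, cfg, seed + k + 2000).session
        res = classify_place_cells(sess)
        for i in np.flatnonzero(gt.is_place):
            n_place += 1
            if res[i].is_place_cell:
                detected += 1
                if res[i].fields:
                    n_centers += 1
                    hits += abs(res[i].fields[0].center_cm - gt.field_center_cm[i]) <= 3.5
    return detected / n_place, hits / max(n_centers, 1)


def _rotation_session_fractions(
    kind: str, p_rotate: float, n_place: int, duration_s: float, seed: int
) -> dict:
    cfg = SimulationConfig(
        duration_s=duration_s, n_cells=n_place, fraction_place_cells=1.0,
        p_rotate=p_rotate, p_stable=1.0 - p_rotate, rng_seed=seed,
    )
    gt = simulate_population(cfg, seed)
    h1, h2, _ = simulate_manipulation_pair(gt, cfg, kind, seed + 10_000)
    sess = combine_halves(h1, h2)
    acfg = AnalysisConfig(n_shuffles_mapcorr=50, rng_seed=seed)
    return analyze_half_pair(sess, acfg).rotation_fractions()


def rotation_recovery(
    p_rotate: float, n_place: int = 150, n_seeds: int = 20,
    duration_s: float = 1200.0, seed: int = 0,
) -> float:
    """Mean estimated rotate fraction on rotate180 sessions."""
    ests = [
        _rotation_session_fractions("rotate180", p_rotate, n_place, duration_s, seed + k)[
            "rotate"
        ]
        for k in range(n_seeds)
    ]
    return float(np.mean(ests))


def rotation_control_wins(
    n_place: int = 150, n_seeds: int = 20, duration_s: float = 1200.0, seed: int = 0
) -> int:
    """Seeds where non_rotate > rotate on stable rotate0 sessions."""
    wins = 0
    for k in range(n_seeds):
        fr = _rotation_session_fractions("rotate0", 0.0, n_place, duration_s, seed + k)
        wins += fr["non_rotate"] > fr["rotate"]
    return wins


def rescale_median_widths(
    kind: str, n_seeds: int = 20, n_cells: int = 40,
    duration_s: float = 600.0, seed: int = 0,
) -> np.ndarray:
    """Per-seed median place-field width change for one rescale kind."""
    meds = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            duration_s=duration_s, n_cells=n_cells, fraction_place_cells=1.0,
            p_rotate=0.0, p_stable=1.0, rng_seed=seed + k,
        )
        gt = simulate_population(cfg, seed + k)
        h1, h2, _ = simulate_manipulation_pair(gt, cfg, kind, seed + k + 20_000)
        res = analyze_half_pair(
            combine_halves(h1, h2), AnalysisConfig(n_shuffles_mapcorr=50, rng_seed=seed + k)
        )
        dw = res.width_changes()
        meds.append(np.median(dw) if dw.size else np.nan)
    return np.asarray(meds)


def speed_null_misclass_rate(
    n_cells: int = 200, n_seeds: int = 20, duration_s: float = 600.0, seed: int = 0
) -> float:
    """Two-tailed misclassification rate of untuned white-noise residuals."""
    wrong = 0
    total = 0
    cfg = SimulationConfig(duration_s=duration_s)
    for k in range(n_seeds):
        sess = _noise_session(cfg, n_cells, seed + 104_729 * (k + 1))
        res = classify_speed_cells(sess)
        wrong += sum(r.speed_class != "none" for r in res)
        total += len(res)
    return wrong / total


def speed_sensitivity(
    n_seeds: int = 5, n_cells: int = 40, duration_s: float = 1200.0, seed: int = 0
) -> float:
    """Sensitivity on constructed speed cells at default tuning slopes."""
    hit = 0
    total = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            duration_s=duration_s, n_cells=n_cells, fraction_place_cells=0.0,
            fraction_speed_pos=0.5, fraction_speed_neg=0.5, rng_seed=seed + k,
        )
        gt = simulate_population(cfg, seed + k)
        traj = simulate_trajectory(cfg, seed + k + 100)
        sess = render_session(gt, traj, cfg, seed + k + 200).session
        res = classify_speed_cells(sess)
        for i in range(n_cells):
            want = {1: "positive", -1: "negative"}.get(gt.speed_class[i])
            if want is not None:
                total += 1
                hit += res[i].speed_class == want
    return hit / total


def decoding_oracle_r(duration_s: float = 600.0, seed: int = 0) -> float:
    """Test-set r when true speed itself is one of the predictors."""
    cfg = SimulationConfig(duration_s=duration_s, n_cells=5, rng_seed=seed)
    gt = simulate_population(cfg, seed)
    traj = simulate_trajectory(cfg, seed + 1)
    sess = render_session(gt, traj, cfg, seed + 2).session
    beh = analyze_behavior(sess)
    rng = np.random.default_rng(seed + 3)
    predictors = np.vstack([beh.speed, rng.standard_normal((4, sess.n_samples))])
    res = decode_speed(sess, 5, behavior=beh, rng=rng, predictors=predictors)
    return res.mean_r


def decoding_null_below_chance(
    n_seeds: int = 20, duration_s: float = 600.0, seed: int = 0
) -> int:
    """Seeds where all-noise predictors decode below the chance threshold."""
    below = 0
    cfg = SimulationConfig(duration_s=duration_s, n_cells=5)
    for k in range(n_seeds):
        sess = _noise_session(cfg, 20, seed + 31 * (k + 1))
        rng = np.random.default_rng(seed + k)
        beh = analyze_behavior(sess)
        res = decode_speed(sess, 16, behavior=beh, rng=rng, predictors=sess.traces)
        below += res.mean_r < res.chance_threshold
    return below


def decoding_cell_count_comparison(
    n_seeds: int = 20, duration_s: float = 1200.0, seed: int = 0
) -> tuple[float, float, int, int]:
    """(mean r at 32 cells, mean r at 8, seeds with r32 > r8, seeds above chance)."""
    r32s, r8s = [], []
    wins = 0
    above = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            duration_s=duration_s, n_cells=32, fraction_place_cells=0.0,
            fraction_speed_pos=0.5, fraction_speed_neg=0.5, rng_seed=seed + k,
        )
        gt = simulate_population(cfg, seed + k)
        traj = simulate_trajectory(cfg, seed + k + 300)
        sess = render_session(gt, traj, cfg, seed + k + 600).session
        beh = analyze_behavior(sess)
        r32 = decode_speed(sess, 32, behavior=beh, rng=np.random.default_rng(seed + k))
        r8 = decode_speed(sess, 8, behavior=beh, rng=np.random.default_rng(seed + k))
        r32s.append(r32.mean_r)
        r8s.append(r8.mean_r)
        wins += r32.mean_r > r8.mean_r
        above += r32.mean_r > r32.chance_threshold
    return float(np.mean(r32s)), float(np.mean(r8s)), wins, above


def popevent_recovery(
    n_seeds: int = 5, n_cells: int = 50, n_events: int = 50,
    duration_s: float = 600.0, seed: int = 0,
) -> tuple[float, float]:
    """(sensitivity to injected synchronous frames, spurious detection rate)."""
    hits = 0
    n_inj = 0
    spurious = 0
    n_det = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            duration_s=duration_s, n_cells=n_cells, popevent_n=n_events,
            popevent_speed_regime="low", rng_seed=seed + k,
        )
        gt = simulate_population(cfg, seed + k)
        traj = simulate_trajectory(cfg, seed + k + 40)
        rr = render_session(gt, traj, cfg, seed + k + 80)
        ev = detect_population_events(event_raster(rr.session.traces))
        inj = gt.popevent_samples
        n_inj += inj.size
        hits += sum(np.abs(ev.event_samples - s).min() <= 1 for s in inj)
        n_det += ev.n_events
        spurious += sum(np.abs(s - inj).min() > 1 for s in ev.event_samples)
    return hits / n_inj, spurious / max(n_det, 1)


def popevent_threshold_monotonic(seed: int = 0) -> bool:
    rng = np.random.default_rng(seed)
    raster = rng.random((40, 3000)) < 0.05
    raster[:, 500:505] = True
    counts = [
        detect_population_events(raster, sd).n_events for sd in (2.0, 3.0, 4.0, 5.0, 6.0)
    ]
    return all(a >= b for a, b in zip(counts, counts[1:]))


def coreg_matching_accuracy(
    n_seeds: int = 20, n_cells: int = 100, jitter_px: float = 2.0, seed: int = 0
) -> float:
    """Matching accuracy against ground-truth identity at p_survive = 0.5."""
    accs = []
    for k in range(n_seeds):
        cfg = SimulationConfig(duration_s=30.0, n_cells=n_cells, p_survive=0.5,
                               footprint_jitter_px=jitter_px, rng_seed=seed + k)
        md = simulate_multiday(cfg, 2, seed + k)
        m = match_cells(md.sessions[0].footprints, md.sessions[1].footprints)
        ids1 = md.ground_truths[0].ids
        ids2 = md.ground_truths[1].ids
        correct = sum(ids1[i] == ids2[j] for i, j in m.pairs)
        accs.append(correct / max(m.pairs.shape[0], 1))
    return float(np.mean(accs))


def turnover_max_error(
    n_seeds: int = 20, n_cells: int = 150, seed: int = 0,
    p_values: tuple = (0.2, 0.5, 0.8),
) -> float:
    """Max |estimated - configured| survival fraction across p_survive values."""
    worst = 0.0
    for p in p_values:
        fracs = []
        for k in range(n_seeds):
            cfg = SimulationConfig(duration_s=30.0, n_cells=n_cells, p_survive=p,
                                   footprint_jitter_px=1.0, rng_seed=seed + k)
            md = simulate_multiday(cfg, 2, seed + k)
            m = match_cells(md.sessions[0].footprints, md.sessions[1].footprints)
            fracs.append(turnover_fraction(m, n_cells, n_cells))
        worst = max(worst, abs(float(np.mean(fracs)) - p))
    return worst


def amplitude_persistence_recovery(
    rho: float = 0.8, n_pairs: int = 200, n_seeds: int = 5,
    duration_s: float = 600.0, seed: int = 0,
) -> float:
    """Mean recovered Spearman r of mean peak amplitude across days."""
    rs = []
    for k in range(n_seeds):
        cfg = SimulationConfig(duration_s=duration_s, n_cells=n_pairs, p_survive=1.0,
                               footprint_jitter_px=1.0, amplitude_persistence=rho,
                               rng_seed=seed + k)
        md = simulate_multiday(cfg, 2, seed + k)
        m = match_cells(md.sessions[0].footprints, md.sessions[1].footprints)
        val = coregistration_validation(
            md.sessions[0], md.sessions[1], m, n_iter=200,
            rng=np.random.default_rng(seed + k),
        )
        rs.append(val.amplitude_r)
    return float(np.mean(rs))


def dissociation_experiment(
    n_seeds: int = 3, n_cells: int = 60, duration_s: float = 600.0, seed: int = 0
) -> tuple[float, float, float]:
    """(mean across-day map r, mean speed-r correlation, mean speed chance).

    The generator redraws place tuning across days but preserves speed
    tuning, so spatial stability collapses while speed stability survives.
    """
    map_rs, sr_rs, chances = [], [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            duration_s=duration_s, n_cells=n_cells, fraction_place_cells=0.5,
            fraction_speed_pos=0.25, fraction_speed_neg=0.25, p_survive=1.0,
            p_keep_place_tuning=0.0, footprint_jitter_px=1.0, rng_seed=seed + k,
        )
        md = simulate_multiday(cfg, 2, seed + k)
        m = match_cells(md.sessions[0].footprints, md.sessions[1].footprints)
        stab = across_day_stability(
            md.sessions[0], md.sessions[1], m, AnalysisConfig(), n_iter=200,
            rng=np.random.default_rng(seed + k),
        )
        map_rs.append(np.nanmean(stab.map_r_across))
        sr_rs.append(stab.speed_r_r)
        chances.append(stab.speed_r_chance)
    return float(np.mean(map_rs)), float(np.mean(sr_rs)), float(np.mean(chances))


def conservation_max_relative_error(
    n_seeds: int = 3, n_cells: int = 10, duration_s: float = 300.0, seed: int = 0
) -> float:
    """Max relative error of sum(map x occupancy) vs sum of masked df/F."""
    worst = 0.0
    for k in range(n_seeds):
        cfg = SimulationConfig(duration_s=duration_s, n_cells=n_cells, rng_seed=seed + k)
        gt = simulate_population(cfg, seed + k)
        traj = simulate_trajectory(cfg, seed + k + 9)
        sess = render_session(gt, traj, cfg, seed + k + 18).session
        beh = analyze_behavior(sess)
        for trace in sess.traces:
            amap = compute_activity_map(trace, beh, 70.0, 9.0, smooth=False)
            total = np.nansum(amap.values * amap.occupancy)
            ref = trace[beh.movement_mask].sum()
            worst = max(worst, abs(total - ref) / max(abs(ref), 1e-12))
    return worst


def pipeline_determinism(tmp_dir: str | Path, seed: int = 0) -> bool:
    """Same session + seed twice: byte-identical result files."""
    tmp_dir = Path(tmp_dir)
    cfg = SimulationConfig(duration_s=300.0, n_cells=10, rng_seed=seed)
    gt = simulate_population(cfg, seed)
    traj = simulate_trajectory(cfg, seed + 1)
    sess = render_session(gt, traj, cfg, seed + 2).session
    digests = []
    for name in ("a", "b"):
        out = tmp_dir / name
        run_pipeline(sess, AnalysisConfig(rng_seed=seed), out)
        digests.append(
            {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
             for f in sorted(out.iterdir())}
        )
    return digests[0] == digests[1]
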
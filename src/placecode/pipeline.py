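"""End-to-end session analysis: dispatch by manipulation, write tidy outputs.

Given a seed, outputs are deterministic byte-for-byte: tables are written
with fixed float formatting and JSON with sorted keys, and every stochastic
stage draws from a generator seeded by the analysis config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import analyze_behavior
from .io_core import AnalysisConfig, Session, filter_cells
from .multiday import across_day_stability, coregistration_validation, match_cells, turnover_fraction
from .population_events import detect_population_events, event_raster, event_speed_profile
from .remapping import analyze_half_pair
from .spatial_coding import classify_place_cells
from .speed_coding import classify_speed_cells
from .trace_metrics import population_peak_stats

FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=float) + "\n")


def analyze_single_session(session: Session, config: AnalysisConfig) -> dict:
    """Place/speed/peak/population-event analysis of one unmanipulated session."""
    behavior = analyze_behavior(session, config)
    kept = filter_cells(session.traces)
    place = classify_place_cells(session, config, behavior)
    speed = classify_speed_cells(session, config, behavior)
    peaks = population_peak_stats(
        session.traces, session.sample_rate_hz, config.peak_prominence_sd
    )
    raster = event_raster(session.traces, config.deconv_threshold_sd)
    events = detect_population_events(raster, config.popevent_threshold_sd)
    per_cell = pd.DataFrame(
        {
            "cell": np.arange(session.n_cells),
            "kept": np.isin(np.arange(session.n_cells), kept.kept_indices),
            "variance": kept.variances,
            "mi_bits": [p.mi for p in place],
            "mi_threshold": [p.threshold for p in place],
            "is_place_cell": [p.is_place_cell for p in place],
            "field_count": [p.field_count for p in place],
            "primary_center_cm": [
                p.primary_field.center_cm if p.primary_field else np.nan for p in place
            ],
            "primary_width_cm": [
                p.primary_field.width_cm if p.primary_field else np.nan for p in place
            ],
            "primary_size_cm2": [
                p.primary_field.size_cm2 if p.primary_field else np.nan for p in place
            ],
            "speed_r": [s.spearman_r for s in speed],
            "speed_class": [s.speed_class for s in speed],
            "peak_rate_hz": [p.peak_rate_hz for p in peaks],
            "mean_peak_amplitude": [p.mean_peak_amplitude for p in peaks],
            "mean_peak_width_s": [
                p.peak_widths_s.mean() if p.n_peaks else np.nan for p in peaks
            ],
            "pnr": [p.peak_to_noise_ratio for p in peaks],
            "popevent_participant": events.participation,
        }
    )
    summary = {
        "n_cells": session.n_cells,
        "n_kept": int(kept.kept_indices.size),
        "fraction_place_cells": float(np.mean([p.is_place_cell for p in place])),
        "fraction_speed_pos": float(np.mean([s.speed_class == "positive" for s in speed])),
        "fraction_speed_neg": float(np.mean([s.speed_class == "negative" for s in speed])),
        "n_population_events": int(events.n_events),
        "path_length_cm": behavior.path_length_cm,
        "movement_fraction": float(behavior.movement_mask.mean()),
    }
    if events.n_events:
        summary["popevent_mean_speed_cm_s"] = event_speed_profile(
            events, behavior
        ).mean_speed_cm_s
    return {"per_cell": per_cell, "summary": summary}


def analyze_manipulation_session(session: Session, config: AnalysisConfig) -> dict:
    """Two-half remapping analysis of a rotation or rescaling session."""
    rng = np.random.default_rng(config.rng_seed)
    res = analyze_half_pair(session, config, rng)
    per_cell = pd.DataFrame(
        {
            "cell": np.arange(session.n_cells),
            "map_r": [c.map_r for c in res.cells],
            "is_place_half1": [c.is_place_1 for c in res.cells],
            "is_place_half2": [c.is_place_2 for c in res.cells],
            "rotation_category": [c.rotation or "" for c in res.cells],
            "width_change_cm": [
                c.width_change_cm if c.width_change_cm is not None else np.nan
                for c in res.cells
            ],
        }
    )
    fr = res.rotation_fractions()
    dw = res.width_changes()
    summary = {
        "manipulation": session.meta.manipulation,
        "chance_threshold": res.chance_threshold,
        "mean_map_r_place1": float(np.nanmean(res.map_correlations()))
        if res.map_correlations().size
        else float("nan"),
        "rotate_fraction": fr["rotate"],
        "non_rotate_fraction": fr["non_rotate"],
        "lost_fraction": fr["lost"],
        "n_outer_place_cells": fr["n_outer"],
        "n_middle_excluded": fr["n_middle_excluded"],
        "median_width_change_cm": float(np.median(dw)) if dw.size else float("nan"),
        "n_width_change_cells": int(dw.size),
    }
    return {"per_cell": per_cell, "summary": summary}


def run_pipeline(
    sessions: Session | list[Session],
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage appropriate to the sessions' manipulation labels.

    With two or more sessions carrying footprints, cross-day matching and
    stability are additionally computed.  Returns the report bundle; writes
    CSV/JSON files when ``out_dir`` is given.
    """
    config = config or AnalysisConfig()
    if isinstance(sessions, Session):
        sessions = [sessions]
    report: dict = {"config": config.to_dict(), "sessions": []}
    tables: dict[str, pd.DataFrame] = {}
    for k, session in enumerate(sessions):
        manip = session.meta.manipulation
        name = f"session{k}_{session.meta.session_id}"
        if manip == "none":
            res = analyze_single_session(session, config)
        else:
            res = analyze_manipulation_session(session, config)
        tables[f"{name}_cells"] = res["per_cell"]
        report["sessions"].append({"name": name, "manipulation": manip, **res["summary"]})
    if len(sessions) >= 2 and all(s.footprints is not None for s in sessions):
        coreg_rows = []
        for a, b in zip(range(len(sessions) - 1), range(1, len(sessions))):
            rng = np.random.default_rng(config.rng_seed + 1000 + a)
            m = match_cells(sessions[a].footprints, sessions[b].footprints, config)
            val = coregistration_validation(sessions[a], sessions[b], m, config, rng)
            stab = across_day_stability(sessions[a], sessions[b], m, config, rng)
            coreg_rows.append(
                {
                    "pair": f"{a}/{b}",
                    "n_matched": int(m.pairs.shape[0]),
                    "turnover_fraction": turnover_fraction(
                        m, sessions[a].n_cells, sessions[b].n_cells
                    ),
                    "amplitude_r": val.amplitude_r,
                    "amplitude_chance": val.amplitude_chance,
                    "pnr_r": val.pnr_r,
                    "map_r_across_mean": float(np.nanmean(stab.map_r_across))
                    if stab.map_r_across.size
                    else float("nan"),
                    "mi_r": stab.mi_r,
                    "speed_r_r": stab.speed_r_r,
                    "speed_r_chance": stab.speed_r_chance,
                }
            )
        tables["coregistration"] = pd.DataFrame(coreg_rows)
        report["coregistration"] = coreg_rows
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            _write_csv(df, out / f"{name}.csv")
        _write_json(report, out / "results.json")
        (out / "run.log").write_text(
            "placecode run\nseed=%d\nconfig=%s\n"
            % (config.rng_seed, json.dumps(config.to_dict(), sort_keys=True))
        )
    report["tables"] = tables
    return report
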
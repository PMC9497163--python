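"""End-to-end orchestration: simulate -> analyze -> report.

A run configuration (YAML mapping; see :data:`DEFAULT_CONFIG`) selects the
stages and their parameters.  A single global seed fans out to per-stage
seeds by fixed offsets so each stage is independently reproducible, and the
whole bundle is deterministic: identical config + seed gives byte-identical
summary JSON.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np

from . import barrier, calcium, chirality, junctions, synthetic, tfm
from .core_io import PatternGeometry, pattern_mask, write_results

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline",
           "STAGE_SEED_OFFSETS"]

#: Fixed per-stage seed offsets from the global seed.
STAGE_SEED_OFFSETS = {"chirality": 101, "junctions": 202, "tfm": 303,
                      "calcium": 404, "barrier": 505}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "pixel_size": 0.645,
    "output_dir": None,
    "stages": ["chirality", "junctions", "tfm", "calcium", "barrier"],
    "chirality": {
        # synthetic "EA vs E0" style contrast: two bias conditions
        "scenarios": {"E0": {"bias_deg": 5.0}, "EA": {"bias_deg": 15.0}},
        "n_rings": 3,
        "kappa": 6.0,
        "image_px": 288,
        "ring_diameter_um": 160.0,
        "band_width_um": 45.0,
        "grid_px": 24,
    },
    "junctions": {"n_cells": 12, "wiggle_amp": 2.5, "wiggle_freq": 3.0,
                  "image_px": 256},
    "tfm": {
        "image_px": 192,
        "youngs_modulus_pa": 5000.0,
        "poisson_ratio": 0.45,
        "scenarios": {"E0": {"magnitude_pa": 100.0},
                      "EA": {"magnitude_pa": 200.0}},
        "tangential_frac": -0.1,
        "n_beads": 2500,
    },
    "calcium": {
        "n_frames": 400,
        "frame_interval_s": 3.0,
        "amplitude_dFF0": 2.0,
        "time_to_peak_s": 6.0,
        "decay_tau_s": 9.0,
        "period_s": 120.0,
        "noise_sd": 2.0,
        "baseline_F": 100.0,
    },
    "barrier": {
        "group_means": {"control": 150.0, "E0": 165.0, "EA": 185.0},
        "group_sds": {"control": 5.0, "E0": 5.0, "EA": 5.0},
        "n_per_group": 8,
        "area_cm2": 4.5,
        "r_m_ohm": 120.0,
        "papp_cm_s": {"control": 30e-6, "E0": 10e-6, "EA": 15e-6},
        "blank_pe_cm_s": 60e-6,
    },
}


def validate_config(cfg: dict) -> dict:
    """Merge a user config over the defaults and check required fields."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in cfg.items():
        if key not in merged:
            raise ValueError(f"unknown config field {key!r}")
        if isinstance(merged.get(key), dict) and isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    for req in ("seed", "pixel_size"):
        if merged.get(req) is None:
            raise ValueError(f"config is missing required field {req!r}")
    if not isinstance(merged["seed"], (int, np.integer)):
        raise ValueError("config field 'seed' must be an integer")
    if merged["pixel_size"] <= 0:
        raise ValueError("config field 'pixel_size' must be > 0")
    unknown = set(merged["stages"]) - set(STAGE_SEED_OFFSETS)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return merged


def _ring_geometry(image_px: int, pixel_size: float, diameter_um: float,
                   band_um: float) -> PatternGeometry:
    half = image_px * pixel_size / 2.0
    return PatternGeometry(kind="ring", center=(half, half),
                           diameter=diameter_um, band_width=band_um)


def _stage_chirality(cfg, seed, pixel_size):
    p = cfg["chirality"]
    geo = _ring_geometry(p["image_px"], pixel_size, p["ring_diameter_um"],
                         p["band_width_um"])
    out = {}
    for si, (name, sc) in enumerate(sorted(p["scenarios"].items())):
        biases = []
        for k in range(p["n_rings"]):
            truth = synthetic.ChiralityTruth(bias_deg=sc["bias_deg"],
                                             kappa=p["kappa"], geometry=geo)
            stack, _ = synthetic.gen_ring_texture(
                truth, (p["image_px"], p["image_px"]),
                seed=seed + 97 * si + k, pixel_size=pixel_size)
            _, summary = chirality.analyze_pattern(
                stack.frame(0), geo, pixel_size, grid_px=p["grid_px"])
            biases.append(summary.mean_bias_deg)
        ring_summary = chirality.summarize_bias(
            [chirality.SubregionResult((0, 0), 0, 1, 1, bias_deg=b)
             for b in biases]) if len(biases) >= 3 else None
        out[name] = {
            "true_bias_deg": sc["bias_deg"],
            "per_ring_mean_bias_deg": [round(b, 4) for b in biases],
            "mean_bias_deg": round(float(np.mean(biases)), 4),
            "classification": (ring_summary.classification
                               if ring_summary else "n/a"),
        }
    return out


def _stage_junctions(cfg, seed, pixel_size):
    p = cfg["junctions"]
    stack, truths = synthetic.gen_junction_network(
        p["n_cells"], p["wiggle_amp"], p["wiggle_freq"],
        (p["image_px"], p["image_px"]), seed=seed, pixel_size=pixel_size)
    skel = junctions.segment_skeleton(stack.frame(0), pixel_size=pixel_size)
    paths = []
    for path in junctions.trace_paths(skel, pixel_size=pixel_size):
        paths.extend(junctions.split_closed(path))
    ratios = []
    for path in paths:
        try:
            res = junctions.tortuosity(path)
        except ValueError:
            continue
        if res.chord_um > 5 * pixel_size:
            ratios.append(res.ratio)
    dist = junctions.boundary_angle_chirality(paths, ap_axis_deg=0.0)
    return {
        "n_paths": len(paths),
        "n_true_edges": len(truths),
        "true_mean_tortuosity": round(float(np.mean([t["ratio"] for t in truths])), 4),
        "measured_mean_tortuosity": round(float(np.mean(ratios)), 4),
        "frac_positive_boundary_angles": round(dist.frac_positive, 4),
        "boundary_binom_p": round(dist.binom_p, 4),
    }


def _stage_tfm(cfg, seed, pixel_size):
    p = cfg["tfm"]
    gel = tfm.GelProperties(p["youngs_modulus_pa"], p["poisson_ratio"])
    shape = (p["image_px"], p["image_px"])
    geo = _ring_geometry(p["image_px"], pixel_size, 0.6 * p["image_px"] * pixel_size,
                         0.25 * p["image_px"] * pixel_size)
    out = {}
    for si, (name, sc) in enumerate(sorted(p["scenarios"].items())):
        tx, ty = synthetic.make_ring_traction(
            geo, shape, pixel_size, magnitude_pa=sc["magnitude_pa"],
            tangential_frac=p["tangential_frac"],
            profile_sigma_um=geo.band_width / 2.5)
        ref, deformed, truth = synthetic.gen_bead_pair(
            tx, ty, gel, n_beads=p["n_beads"], image_shape=shape,
            seed=seed + si, pixel_size=pixel_size)
        disp = tfm.piv(ref.frame(0), deformed.frame(0), window_px=32,
                       overlap_frac=0.75, pixel_size=pixel_size)
        trac = tfm.reconstruct_traction(disp, gel, lambda_reg="lcurve")
        ring = tfm.ring_decomposition(trac, geo)
        out[name] = {
            "true_magnitude_pa": sc["magnitude_pa"],
            "mean_radial_pa": round(ring.mean_radial_pa, 4),
            "mean_tangential_pa": round(ring.mean_tangential_pa, 4),
            "net_moment_sign": int(np.sign(ring.net_moment_pa_um)),
            "balance_residual": round(ring.balance_residual, 5),
            "mean_traction_pa": round(float(trac.magnitude.mean()), 4),
        }
    names = sorted(p["scenarios"])
    if len(names) == 2:
        a, b = names
        out["traction_ratio"] = round(
            out[b]["mean_traction_pa"] / out[a]["mean_traction_pa"], 4)
    return out


def _stage_calcium(cfg, seed, pixel_size):
    p = cfg["calcium"]
    truths = []
    t0 = 30.0
    while t0 + p["time_to_peak_s"] + 3 * p["decay_tau_s"] \
            < p["n_frames"] * p["frame_interval_s"] - 30.0:
        truths.append(synthetic.SparkTruth(
            onset_s=t0, amplitude_dFF0=p["amplitude_dFF0"],
            time_to_peak_s=p["time_to_peak_s"], decay_tau_s=p["decay_tau_s"],
            baseline_F=p["baseline_F"], noise_sd=p["noise_sd"]))
        t0 += p["period_s"]
    trace, _ = synthetic.gen_calcium_trace(
        truths, n_frames=p["n_frames"],
        frame_interval=p["frame_interval_s"], seed=seed)
    events = [calcium.spark_parameters(trace, e)
              for e in calcium.detect_sparks(trace)]
    stats = calcium.oscillation_stats(events) if events else {}
    return {
        "n_true_events": len(truths),
        "n_detected": len(events),
        "amplitude_mean_dFF0": round(stats["amplitude_dFF0"]["mean"], 4),
        "tau_mean_s": round(stats["decay_tau_s"]["mean"], 4),
        "interpeak_mean_s": round(stats["interpeak_interval_s"]["mean"], 4),
    }


def _stage_barrier(cfg, seed, pixel_size):
    p = cfg["barrier"]
    records = synthetic.gen_barrier_records(
        p["group_means"], p["group_sds"], p["n_per_group"],
        area_cm2=p["area_cm2"], seed=seed, r_m_ohm=p["r_m_ohm"])
    groups = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(rec.teer_ohm_cm2)
    out = {"teer_mean_ohm_cm2": {g: round(float(np.mean(v)), 3)
                                 for g, v in sorted(groups.items())}}
    names = sorted(groups)
    comparisons = {}
    base = "control" if "control" in groups else names[0]
    for other in names:
        if other == base:
            continue
        cmpres = barrier.compare_groups(groups[base], groups[other])
        comparisons[f"{base}_vs_{other}"] = {
            "p_two_tailed": round(cmpres.p_two_tailed, 6),
            "fold_change": round(cmpres.fold_change, 4)}
    out["teer_comparisons"] = comparisons
    pe = {}
    for gi, (g, papp) in enumerate(sorted(p["papp_cm_s"].items())):
        series = synthetic.make_permeability_series(
            papp, area_cm2=p["area_cm2"], noise_frac=0.02, seed=seed + gi)
        rec = barrier.permeability(series, donor_c0=100.0,
                                   area_cm2=p["area_cm2"],
                                   blank_pe=p["blank_pe_cm_s"], group=g)
        pe[g] = round(rec.pe_endothelial * 1e6, 4)
    out["pe_endothelial_1e-6_cm_s"] = pe
    return out, records


_STAGES = {"chirality": _stage_chirality, "junctions": _stage_junctions,
           "tfm": _stage_tfm, "calcium": _stage_calcium}


def run_pipeline(config: dict) -> dict:
    """Run the configured stages on synthetic data and return the summary.

    If ``output_dir`` is set, per-stage tables and ``summary.json`` are
    written there; the JSON is byte-stable for a fixed config + seed.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    px = float(cfg["pixel_size"])
    summary = {"seed": seed, "pixel_size_um": px}
    teer_records = None
    for stage in cfg["stages"]:
        sseed = seed + STAGE_SEED_OFFSETS[stage]
        if stage == "barrier":
            summary["barrier"], teer_records = _stage_barrier(cfg, sseed, px)
        else:
            summary[stage] = _STAGES[stage](cfg, sseed, px)
    if cfg["output_dir"]:
        outdir = Path(cfg["output_dir"])
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
        if teer_records is not None:
            write_results(teer_records, outdir / "teer_records.csv")
    return summary
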
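"""End-to-end orchestration on synthetic sessions plus anatomical maps.

Stages: design the stimulus battery, simulate a ground-truth population,
run the full-field response analysis (amplitudes, opponency, MR), score
recovered labels against ground truth, and build moving-window anatomical
property maps. Everything is reproducible from the config's seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import respanalysis as ra
from . import stimdesign as sd
from . import synthdata as syn

logger = logging.getLogger("chromlgn")

__all__ = [
    "DEFAULT_CONFIG",
    "SessionConfig",
    "AnatomicalMap",
    "moving_window_map",
    "design_stimulus_battery",
    "run_pipeline",
]

DEFAULT_CONFIG = {
    "seeds": {"population": 1, "simulation": 2, "analysis": 3},
    "population": {"n": 400, "prevalences": None, "parameter_ranges": None,
                   "medial_clustering": True},
    "stimuli": {"contrast": 0.75, "frequency": 0.25, "fwhm_nm": 20.0,
                "ramp_ms": 40.0},
    "protocol": {"n_trials": 30, "n_blocks": 5, "step_trials": 10,
                 "step_intensities": [0], "cycles_per_trial": 1},
    "analysis": {"n_shuffles": 100, "alpha": 0.05},
    "out_dir": None,
    "verbose": False,
}

#: Prevalence preset for high-SNR recovery benchmarks: mostly responsive
#: cells, opponent fraction of responsive cells ~0.35.
HIGH_SNR_PREVALENCES = {
    "nonopp_ON": 0.35, "nonopp_OFF": 0.17,
    "L_ON_S_OFF": 0.14, "S_ON_L_OFF": 0.14,
    "nonresponsive": 0.20,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class SessionConfig:
    """Validated pipeline configuration; see DEFAULT_CONFIG for keys."""

    raw: dict

    def __post_init__(self):
        self.raw = _merge(DEFAULT_CONFIG, self.raw)
        for key in ("population", "simulation", "analysis"):
            seed = self.raw["seeds"].get(key)
            if not isinstance(seed, (int, np.integer)):
                raise ValueError(f"stage {key!r} needs an integer seed, "
                                 f"got {seed!r}")

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnatomicalMap:
    """Moving-window aggregate over anatomical (x_ml, y_dv) coordinates."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray             # (n_y, n_x); NaN where masked
    counts: np.ndarray
    radius: float
    min_count: int

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.xs, self.ys)
        return pd.DataFrame({"x_ml": X.ravel(), "y_dv": Y.ravel(),
                             "value": self.values.ravel(),
                             "count": self.counts.ravel()})


def moving_window_map(cells, radius: float = 150.0, min_count: int = 10,
                      target=("mean",), grid_step: float = 25.0) -> AnatomicalMap:
    """Aggregate a per-cell value or label fraction in a circular window.

    ``cells`` is an iterable of (x_um, y_um, value) where value is numeric
    for ``target=("mean",)`` or any label for ``target=("fraction", lab)``.
    Grid nodes with fewer than ``min_count`` cells in the window are masked.
    """
    cells = list(cells)
    if not cells:
        return AnatomicalMap(np.empty(0), np.empty(0),
                             np.empty((0, 0)), np.empty((0, 0), int),
                             radius, min_count)
    xy = np.array([(c[0], c[1]) for c in cells], float)
    if target[0] == "mean":
        vals = np.array([float(c[2]) for c in cells])
    elif target[0] == "fraction":
        vals = np.array([1.0 if c[2] == target[1] else 0.0 for c in cells])
    else:
        raise ValueError("target must be ('mean',) or ('fraction', label)")
    xs = np.arange(xy[:, 0].min(), xy[:, 0].max() + grid_step / 2, grid_step)
    ys = np.arange(xy[:, 1].min(), xy[:, 1].max() + grid_step / 2, grid_step)
    values = np.full((len(ys), len(xs)), np.nan)
    counts = np.zeros((len(ys), len(xs)), int)
    r2 = radius ** 2
    for iy, y in enumerate(ys):
        d2y = (xy[:, 1] - y) ** 2
        for ix, x in enumerate(xs):
            sel = (xy[:, 0] - x) ** 2 + d2y <= r2
            n = int(sel.sum())
            counts[iy, ix] = n
            if n >= min_count:
                values[iy, ix] = vals[sel].mean()
    return AnatomicalMap(xs, ys, values, counts, radius, min_count)


FULL_FIELD_STIMULI = ("L_Only", "S_Only", "L+S", "L-S")


def design_stimulus_battery(contrast: float = 0.75, fwhm_nm: float = 20.0):
    """Solve the four cone stimuli plus rod stimulus on the default hardware.

    Returns (primaries, background, solutions dict).
    """
    prims = sd.default_primaries(fwhm_nm=fwhm_nm)
    bg = sd.make_background(prims)
    c = contrast
    specs = {
        "L_Only": sd.ContrastSpec.isolate("L", c, ["S"], ["rod", "mel"]),
        "S_Only": sd.ContrastSpec.isolate("S", c, ["L"], ["rod", "mel"]),
        "L+S": sd.ContrastSpec({"L": ("target", c), "S": ("target", c),
                                "rod": ("minimize", None),
                                "mel": ("minimize", None)}),
        "L-S": sd.ContrastSpec({"L": ("target", c), "S": ("target", -c),
                                "rod": ("minimize", None),
                                "mel": ("minimize", None)}),
        "Rod": sd.ContrastSpec({"rod": ("target", 0.45),
                                "L": ("silenced", 0.0),
                                "S": ("silenced", 0.0)}),
    }
    sols = {k: sd.solve_silent_substitution(prims, bg, v)
            for k, v in specs.items()}
    return prims, bg, sols


def _block_amplitudes(trains, period, n_blocks):
    """Per-block smoothed peak-trough amplitudes (blocks of equal size)."""
    per = max(len(trains) // n_blocks, 1)
    amps = []
    for b in range(n_blocks):
        block = trains[b * per:(b + 1) * per]
        if not block:
            break
        h = ra.cycle_histogram(block, period)
        amps.append(float(h.smoothed.max() - h.smoothed.min()))
    return amps


def run_pipeline(config: dict | SessionConfig | None = None) -> dict:
    """Design stimuli, simulate, analyze, and score against ground truth.

    Returns a report dict with the per-unit results table, confusion
    matrices, accuracies, anatomical maps and provenance. When
    ``config["out_dir"]`` is set, results are also written as CSV/JSON.
    """
    cfg = config if isinstance(config, SessionConfig) else SessionConfig(config or {})
    t_start = time.time()
    seeds = cfg["seeds"]
    stim_cfg, proto = cfg["stimuli"], cfg["protocol"]

    logger.info("stage 1: stimulus design")
    prims, bg, sols = design_stimulus_battery(stim_cfg["contrast"],
                                              stim_cfg["fwhm_nm"])
    period = 1.0 / stim_cfg["frequency"]
    wfs = {k: sd.build_square_wave(sols[k], prims, bg, stim_cfg["frequency"],
                                   stim_cfg["ramp_ms"],
                                   n_cycles=proto["cycles_per_trial"])
           for k in FULL_FIELD_STIMULI}
    high, low = sd.build_step_pair(prims, sample_rate=50.0)

    logger.info("stage 2: population and simulation")
    pop_cfg = cfg["population"]
    population = syn.make_population(
        pop_cfg["n"], pop_cfg["prevalences"], pop_cfg["parameter_ranges"],
        seed=seeds["population"],
        medial_clustering=pop_cfg["medial_clustering"])
    spikes = {}
    for i, (name, wf) in enumerate(wfs.items()):
        spikes[name] = syn.simulate_full_field(
            population, wf, proto["n_trials"], seed=seeds["simulation"] + i)
    step_spikes = {}
    for j, intensity in enumerate(proto["step_intensities"]):
        step_spikes[intensity] = syn.simulate_step_pair(
            population, high, low, proto["step_trials"],
            seed=seeds["simulation"] + 100 + j)

    logger.info("stage 3: per-unit analysis")
    n_shuffles = cfg["analysis"]["n_shuffles"]
    alpha = cfg["analysis"]["alpha"]
    rows = []
    for neuron in population.neurons:
        uid = neuron.unit_id
        mL = ra.response_amplitude(spikes["L_Only"][uid], period, n_shuffles,
                                   seed=seeds["analysis"] + uid)
        mS = ra.response_amplitude(spikes["S_Only"][uid], period, n_shuffles,
                                   seed=seeds["analysis"] + 10000 + uid)
        tw = {k: _block_amplitudes(spikes[k2][uid], period, proto["n_blocks"])
              for k, k2 in (("L-S", "L-S"), ("L+S", "L+S"))}
        call = ra.classify_opponency(mL, mS, float(np.mean(tw["L-S"])),
                                     float(np.mean(tw["L+S"])), tw, alpha)
        pref = np.nan
        if mL.corrected_amplitude > 0 or mS.corrected_amplitude > 0:
            pref = ra.cone_preference(max(mL.corrected_amplitude, 0.0),
                                      max(mS.corrected_amplitude, 0.0))
        mr = ra.classify_mr({k: v[uid] for k, v in step_spikes.items()},
                            pre_s=high.meta["pre_s"], step_s=high.meta["step_s"],
                            alpha=alpha)
        # periodogram on the L-S trial-mean rate series at the stimulus period
        series = np.concatenate([
            ra.cycle_histogram([tr], period).rates
            for tr in spikes["L-S"][uid][:proto["n_blocks"]]])
        pgram = ra.chi2_periodogram(series, ra.N_BINS)
        truth = {"nonopp_ON": "non_opponent", "nonopp_OFF": "non_opponent",
                 "nonresponsive": "non_responsive"}.get(neuron.class_label,
                                                        neuron.class_label)
        rows.append({
            "unit_id": uid, "truth_class": neuron.class_label,
            "truth_opponency": truth, "opponency": call.label,
            "evidence": call.evidence,
            "L_amp": mL.corrected_amplitude, "S_amp": mS.corrected_amplitude,
            "L_sig": mL.significant, "S_sig": mS.significant,
            "L_polarity": mL.polarity, "S_polarity": mS.polarity,
            "cone_preference": pref,
            "periodogram_pct": pgram.percent_variance,
            "mr": mr.label, "truth_mr": "MR" if neuron.mr_flag else "non_MR",
            "x_ml": neuron.anatomy[0], "y_dv": neuron.anatomy[1],
            "elevation": neuron.rf_center[1],
        })
    results = pd.DataFrame(rows)

    logger.info("stage 4: scoring and maps")
    opp_conf = pd.crosstab(results["truth_opponency"], results["opponency"])
    mr_conf = pd.crosstab(results["truth_mr"], results["mr"])
    opp_acc = float((results["truth_opponency"] == results["opponency"]).mean())
    mr_acc = float((results["truth_mr"] == results["mr"]).mean())
    opponent = results["opponency"].isin(["L_ON_S_OFF", "S_ON_L_OFF"])
    prevalence_map = moving_window_map(
        [(r.x_ml, r.y_dv, "opp" if o else "non")
         for r, o in zip(results.itertuples(), opponent)],
        target=("fraction", "opp"))

    report = {
        "config_hash": cfg.hash, "seeds": dict(seeds),
        "results": results,
        "opponency_confusion": opp_conf, "opponency_accuracy": opp_acc,
        "mr_confusion": mr_conf, "mr_accuracy": mr_acc,
        "solutions": sols, "background": bg,
        "prevalence_map": prevalence_map,
        "elapsed_s": time.time() - t_start,
    }
    out_dir = cfg["out_dir"]
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "per_unit_results.csv", index=False)
        opp_conf.to_csv(out / "opponency_confusion.csv")
        mr_conf.to_csv(out / "mr_confusion.csv")
        prevalence_map.to_frame().to_csv(out / "opponency_prevalence_map.csv",
                                         index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"config_hash": cfg.hash, "seeds": dict(seeds),
                       "opponency_accuracy": opp_acc, "mr_accuracy": mr_acc,
                       "n_units": len(results),
                       "solutions": {k: json.loads(s.to_json())
                                     for k, s in sols.items()},
                       "elapsed_s": report["elapsed_s"]}, fh, indent=2)
    return report
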
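"""Ground-truth model neurons and trial-structured spike-train synthesis.

A rectified-linear LN-Poisson rate model with one latency per neuron and an
exponential low-pass on the melanopsin input generates spikes for full-field
modulations, step pairs, spatially patterned stimuli and white noise, with
class labels retained so downstream classification can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import erf

from .stimdesign import OPSINS, Waveform

__all__ = [
    "CLASS_LABELS",
    "NeuronSpec",
    "TrialSpikes",
    "Population",
    "DEFAULT_PREVALENCES",
    "SpatialEvent",
    "make_population",
    "simulate_full_field",
    "simulate_step_pair",
    "simulate_spatial",
    "simulate_white_noise",
    "spikes_to_frame",
    "spikes_from_frame",
]

CLASS_LABELS = ("nonopp_ON", "nonopp_OFF", "L_ON_S_OFF", "S_ON_L_OFF",
                "nonresponsive")

#: Default class prevalences: opponent classes make up ~35% of responsive
#: cells (283 non-opponent vs 150 opponent among 433 responsive out of 715).
DEFAULT_PREVALENCES = {
    "nonopp_ON": 0.28, "nonopp_OFF": 0.11,
    "L_ON_S_OFF": 0.105, "S_ON_L_OFF": 0.105,
    "nonresponsive": 0.40,
}


@dataclass
class NeuronSpec:
    """Generative parameters of one model neuron (ground truth)."""

    unit_id: int
    class_label: str
    w_L: float
    w_S: float
    w_rod: float = 0.0
    w_mel: float = 0.0
    baseline_rate: float = 5.0
    gain: float = 1.0
    latency: float = 0.05
    tau_mel: float = 2.0
    mel_delay: float = 0.3
    rf_center: tuple = (0.0, 20.0)        # (azimuth deg, elevation deg)
    rf_center_diameter: float = 12.0      # degrees
    surround_weight: float = 0.0
    anatomy: tuple = (0.0, 0.0)           # (x_ml um, y_dv um)
    mr_flag: bool = False
    on_off: bool = False                  # absolute-value spatial drive

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be nonnegative")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        self._check_signs()
        if self.mr_flag and self.w_mel <= 0:
            raise ValueError("mr_flag requires w_mel > 0")

    def _check_signs(self):
        lab = self.class_label
        sL, sS = np.sign(self.w_L), np.sign(self.w_S)
        if lab == "L_ON_S_OFF" and not (sL > 0 and sS < 0):
            raise ValueError("L_ON_S_OFF requires w_L > 0 and w_S < 0")
        if lab == "S_ON_L_OFF" and not (sS > 0 and sL < 0):
            raise ValueError("S_ON_L_OFF requires w_S > 0 and w_L < 0")
        if lab in ("nonopp_ON", "nonopp_OFF"):
            want = 1 if lab == "nonopp_ON" else -1
            for s in (sL, sS):
                if s != 0 and s != want:
                    raise ValueError(f"{lab} requires consistent weight signs")
            if sL == 0 and sS == 0:
                raise ValueError(f"{lab} requires a nonzero cone weight")

    @property
    def surround_diameter(self) -> float:
        return 3.0 * self.rf_center_diameter

    def weights(self) -> np.ndarray:
        """Cone/rod weight vector in OPSINS order (mel handled separately)."""
        return np.array([self.w_S, self.w_L, self.w_rod, 0.0])


@dataclass
class TrialSpikes:
    """Spike times (s, relative to trial onset) for one unit and trial."""

    unit_id: int
    trial: int
    times: np.ndarray
    duration: float = np.inf

    def __post_init__(self):
        t = np.sort(np.asarray(self.times, dtype=float))
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")
        self.times = t


@dataclass
class Population:
    neurons: list
    seed: int
    prevalences: dict

    def __post_init__(self):
        if len(self.neurons) == 0:
            raise ValueError("empty population")

    def __len__(self):
        return len(self.neurons)

    def labels(self) -> dict:
        return {n.unit_id: n.class_label for n in self.neurons}

    def to_json(self, path=None):
        payload = {"seed": self.seed, "prevalences": self.prevalences,
                   "neurons": [asdict(n) for n in self.neurons]}
        s = json.dumps(payload, indent=1, default=lambda o: list(o)
                       if isinstance(o, (tuple, np.ndarray)) else float(o))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def make_population(n: int, prevalences: dict | None = None,
                    parameter_ranges: dict | None = None,
                    seed: int = 0, medial_clustering: bool = True) -> Population:
    """Sample ``n`` ground-truth neurons with the given class prevalences.

    Opponent cells cluster medially (low x_ml) in the anatomical template
    when ``medial_clustering`` is set; cone preference of sampled weights
    trends S-ward with RF elevation, mirroring the opsin gradient.
    """
    prevalences = dict(prevalences or DEFAULT_PREVALENCES)
    p = np.array([prevalences.get(lab, 0.0) for lab in CLASS_LABELS])
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("prevalences must be nonnegative and sum to 1")
    ranges = {
        "weight": (15.0, 40.0),       # spikes/s per unit contrast
        "baseline": (4.0, 12.0),
        "gain": (0.8, 1.2),
        "latency": (0.04, 0.08),
        "tau_mel": (1.5, 2.5),
        "azimuth": (-30.0, 60.0),
        "elevation": (-10.0, 60.0),
        "diameter": (6.0, 20.0),
        "mr_fraction": 0.45,
        "w_mel": (10.0, 25.0),
    }
    ranges.update(parameter_ranges or {})
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(CLASS_LABELS), size=n, p=p / p.sum())

    neurons = []
    for i, li in enumerate(labels):
        lab = CLASS_LABELS[li]
        wlo, whi = ranges["weight"]
        elev = rng.uniform(*ranges["elevation"])
        # S-bias grows with elevation (upper visual field = ventral retina)
        s_frac = np.clip(0.2 + 0.6 * (elev - ranges["elevation"][0])
                         / (ranges["elevation"][1] - ranges["elevation"][0])
                         + rng.normal(0, 0.08), 0.05, 0.95)
        mag = rng.uniform(wlo, whi)
        wL, wS = mag * (1 - s_frac), mag * s_frac
        if lab == "nonopp_ON":
            w_L, w_S = wL, wS
        elif lab == "nonopp_OFF":
            w_L, w_S = -wL, -wS
        elif lab == "L_ON_S_OFF":
            w_L, w_S = wL, -wS
        elif lab == "S_ON_L_OFF":
            w_L, w_S = -wL, wS
        else:
            w_L = w_S = 0.0
        opponent = lab in ("L_ON_S_OFF", "S_ON_L_OFF")
        mr = bool(rng.random() < ranges["mr_fraction"]) and lab != "nonresponsive"
        if medial_clustering:
            x_ml = rng.uniform(50.0, 500.0) if opponent else rng.uniform(250.0, 900.0)
        else:
            x_ml = rng.uniform(50.0, 900.0)
        baseline = rng.uniform(*ranges["baseline"])
        gain = rng.uniform(*ranges["gain"])
        # MR cells: mel weight large enough that the sustained difference
        # survives rectification even when the cone drive is suppressive
        w_mel = 0.0
        if mr:
            floor = max(0.0, -gain * (w_L + w_S) - baseline)
            w_mel = floor + rng.uniform(*ranges["w_mel"])
        neurons.append(NeuronSpec(
            unit_id=i, class_label=lab,
            w_L=w_L, w_S=w_S, w_rod=0.0,
            w_mel=w_mel,
            baseline_rate=baseline,
            gain=gain,
            latency=rng.uniform(*ranges["latency"]),
            tau_mel=rng.uniform(*ranges["tau_mel"]),
            rf_center=(rng.uniform(*ranges["azimuth"]), elev),
            rf_center_diameter=rng.uniform(*ranges["diameter"]),
            surround_weight=rng.uniform(0.2, 0.7),
            anatomy=(x_ml, rng.uniform(50.0, 800.0)),
            mr_flag=mr,
        ))
    return Population(neurons, seed, prevalences)


def _mel_kernel(tau: float, dt: float, n_taps: int | None = None) -> np.ndarray:
    """Causal exponential low-pass kernel, unit area."""
    if n_taps is None:
        n_taps = max(int(round(5 * tau / dt)), 1)
    k = np.exp(-np.arange(n_taps) * dt / tau)
    return k / k.sum()


def _poisson_spikes(rate: np.ndarray, dt: float, n_trials: int,
                    rng: np.random.Generator):
    """Inhomogeneous Poisson sampling: per-bin counts, jittered in-bin times."""
    lam = np.clip(rate, 0.0, None) * dt
    counts = rng.poisson(lam[None, :].repeat(n_trials, axis=0))
    out = []
    for tr in range(n_trials):
        idx = np.nonzero(counts[tr])[0]
        reps = counts[tr, idx]
        starts = np.repeat(idx, reps) * dt
        times = starts + rng.random(starts.size) * dt
        out.append(np.sort(times))
    return out


def _rate_from_waveform(neuron: NeuronSpec, wf: Waveform) -> np.ndarray:
    """Rectified-linear LN rate for a full-field waveform's contrast traces."""
    dt = 1.0 / wf.sample_rate
    shift = int(round(neuron.latency / dt))
    c = wf.contrasts
    cone = (neuron.gain
            * (neuron.w_L * c[:, OPSINS.index("L")]
               + neuron.w_S * c[:, OPSINS.index("S")]
               + neuron.w_rod * c[:, OPSINS.index("rod")]))
    cone = np.concatenate([np.zeros(shift), cone])[:len(c)] if shift else cone
    drive = cone
    if neuron.w_mel != 0.0:
        # sluggish pathway: onset delay then exponential low-pass
        k = _mel_kernel(neuron.tau_mel, dt)
        mel = np.convolve(c[:, OPSINS.index("mel")], k)[:len(c)]
        d = int(round(neuron.mel_delay / dt))
        if d:
            mel = np.concatenate([np.zeros(d), mel])[:len(c)]
        drive = drive + neuron.w_mel * mel
    return np.clip(neuron.baseline_rate + drive, 0.0, None)


def simulate_full_field(population: Population, waveform: Waveform,
                        n_trials: int = 30, seed: int = 0) -> dict:
    """Spike trains for each neuron over repeated presentations.

    Returns ``{unit_id: [TrialSpikes, ...]}``; reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / waveform.sample_rate
    dur = waveform.duration
    out = {}
    for neuron in population.neurons:
        rate = _rate_from_waveform(neuron, waveform)
        trains = _poisson_spikes(rate, dt, n_trials, rng)
        out[neuron.unit_id] = [TrialSpikes(neuron.unit_id, tr, t, dur)
                               for tr, t in enumerate(trains)]
    return out


def simulate_step_pair(population: Population, high: Waveform, low: Waveform,
                       n_trials: int = 10, seed: int = 0) -> dict:
    """Spikes for the melanopsin-high/-low step pair.

    Returns ``{unit_id: {"high": [...], "low": [...]}}``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for neuron in population.neurons:
        entry = {}
        for label, wf in (("high", high), ("low", low)):
            rate = _rate_from_waveform(neuron, wf)
            trains = _poisson_spikes(rate, 1.0 / wf.sample_rate, n_trials, rng)
            entry[label] = [TrialSpikes(neuron.unit_id, tr, t, wf.duration)
                            for tr, t in enumerate(trains)]
        out[neuron.unit_id] = entry
    return out


@dataclass(frozen=True)
class SpatialEvent:
    """One bar/square appearance."""

    trial: int
    onset: float                  # s within trial
    azimuth: float                # deg (bar: center of bar; square: center)
    elevation: float
    polarity: int                 # +1 light, -1 dark
    width: float = 6.0            # deg; extent on azimuth axis
    height: float = 6.0           # deg; extent on elevation axis
    opsin_channel: str = "lum"    # "L", "S" or "lum" (both cones)
    contrast: float = 0.72


def _gauss_overlap(center: float, sigma: float, lo: float, hi: float) -> float:
    """Integral of a unit-area 1-D Gaussian over [lo, hi]."""
    s2 = sigma * np.sqrt(2.0)
    return 0.5 * (erf((hi - center) / s2) - erf((lo - center) / s2))


def spatial_drive(neuron: NeuronSpec, ev: SpatialEvent) -> float:
    """Center-minus-surround overlap drive of one event on one neuron."""
    cx, cy = neuron.rf_center
    sc = neuron.rf_center_diameter / 4.0
    ss = neuron.surround_diameter / 4.0
    lo_a, hi_a = ev.azimuth - ev.width / 2, ev.azimuth + ev.width / 2
    lo_e, hi_e = ev.elevation - ev.height / 2, ev.elevation + ev.height / 2
    ov_c = (_gauss_overlap(cx, sc, lo_a, hi_a) * _gauss_overlap(cy, sc, lo_e, hi_e))
    ov_s = (_gauss_overlap(cx, ss, lo_a, hi_a) * _gauss_overlap(cy, ss, lo_e, hi_e))
    spatial = ov_c - neuron.surround_weight * ov_s
    if ev.opsin_channel == "L":
        w = neuron.w_L
    elif ev.opsin_channel == "S":
        w = neuron.w_S
    elif ev.opsin_channel == "lum":
        w = neuron.w_L + neuron.w_S
    else:
        raise ValueError(f"unknown opsin channel {ev.opsin_channel!r}")
    return ev.polarity * ev.contrast * w * spatial


def simulate_spatial(population: Population, events: list, seed: int = 0,
                     trial_duration: float | None = None,
                     response_duration: float = 0.08,
                     drive_scale: float = 40.0) -> dict:
    """Event-based spatial simulation: baseline Poisson plus transient bursts.

    Each event adds ``Poisson(drive_scale * gain * relu(drive) * dur)`` extra
    spikes in a window starting one latency after onset (``|drive|`` for
    ON-OFF cells). Returns ``{unit_id: [TrialSpikes, ...]}``.
    """
    rng = np.random.default_rng(seed)
    trials = sorted({ev.trial for ev in events})
    if trial_duration is None:
        trial_duration = max(ev.onset for ev in events) + 1.0
    out = {}
    for neuron in population.neurons:
        trains = []
        for tr in trials:
            n_base = rng.poisson(neuron.baseline_rate * trial_duration)
            times = [rng.random(n_base) * trial_duration]
            for ev in events:
                if ev.trial != tr:
                    continue
                drive = spatial_drive(neuron, ev)
                drive = abs(drive) if neuron.on_off else max(drive, 0.0)
                lam = drive_scale * neuron.gain * drive * response_duration
                if lam <= 0:
                    continue
                k = rng.poisson(lam)
                if k:
                    t0 = ev.onset + neuron.latency
                    times.append(t0 + rng.random(k) * response_duration)
            all_t = np.concatenate(times)
            all_t = all_t[all_t < trial_duration]
            trains.append(TrialSpikes(neuron.unit_id, tr, all_t, trial_duration))
        out[neuron.unit_id] = trains
    return out


def simulate_white_noise(population: Population, noise: Waveform,
                         seed: int = 0, kernel_taus: float = 0.08) -> tuple:
    """LN-Poisson spikes from white-noise contrast sequences.

    Each opsin input is filtered by a causal exponential kernel (time
    constant ``kernel_taus``) delayed by the neuron's latency. Returns
    ``(spikes, kernels)`` where ``kernels[unit_id]`` is the (n_lags, 3)
    ground-truth filter over [rod, L, S] at the frame rate.
    """
    if noise.kind != "noise":
        raise ValueError("waveform must come from build_white_noise")
    rng = np.random.default_rng(seed)
    dt = 1.0 / noise.sample_rate
    seqs = noise.contrasts[:, [OPSINS.index("rod"), OPSINS.index("L"),
                               OPSINS.index("S")]]
    n = len(seqs)
    out, kernels = {}, {}
    for neuron in population.neurons:
        lag0 = int(round(neuron.latency / dt))
        n_lags = lag0 + max(int(round(3 * kernel_taus / dt)), 1) + 1
        k_shape = np.zeros(n_lags)
        decay = np.exp(-np.arange(n_lags - lag0) * dt / kernel_taus)
        k_shape[lag0:] = decay / decay.sum()
        w = np.array([neuron.w_rod, neuron.w_L, neuron.w_S])
        kern = k_shape[:, None] * w[None, :]
        kernels[neuron.unit_id] = kern
        drive = np.zeros(n)
        for j in range(3):
            if w[j] != 0.0:
                drive += np.convolve(seqs[:, j], kern[:, j])[:n]
        rate = np.clip(neuron.baseline_rate + neuron.gain * drive, 0.0, None)
        trains = _poisson_spikes(rate, dt, 1, rng)
        out[neuron.unit_id] = [TrialSpikes(neuron.unit_id, 0, trains[0],
                                           noise.duration)]
    return out, kernels


def spikes_to_frame(spikes: dict):
    """Flatten ``{unit: [TrialSpikes]}`` to a unit/trial/time DataFrame."""
    import pandas as pd
    rows = []
    for unit_id, trains in spikes.items():
        for ts in trains:
            for t in ts.times:
                rows.append((unit_id, ts.trial, t))
    return pd.DataFrame(rows, columns=["unit_id", "trial", "time_s"])


def spikes_from_frame(df, duration: float = np.inf) -> dict:
    """Inverse of :func:`spikes_to_frame`."""
    out = {}
    for (unit_id, trial), grp in df.groupby(["unit_id", "trial"]):
        out.setdefault(int(unit_id), []).append(
            TrialSpikes(int(unit_id), int(trial),
                        grp["time_s"].to_numpy(), duration))
    return out
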
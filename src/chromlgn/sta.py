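"""Spike-triggered averaging of rod/L/S contrast sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["STAResult", "compute_sta"]

#: lags (s) considered "immediately preceding" for polarity determination
POLARITY_WINDOW_S = 0.3


@dataclass
class STAResult:
    """Per-opsin mean pre-spike contrast over lags at the frame rate."""

    opsin: str
    lags: np.ndarray              # s, 0 = frame containing the spike
    trace: np.ndarray             # mean contrast per lag
    amplitude: float              # peak - trough
    polarity: str                 # "ON" or "OFF"
    shuffled_floor: float         # mean shuffle amplitude
    n_spikes: int
    empty: bool = False


def _sta_matrix(seq: np.ndarray, frame_idx: np.ndarray, n_lags: int) -> np.ndarray:
    """Mean of seq over pre-spike lag windows; lag l = frame_idx - l."""
    out = np.zeros(n_lags)
    for l in range(n_lags):
        idx = frame_idx - l
        valid = idx >= 0
        out[l] = seq[idx[valid]].mean() if valid.any() else 0.0
    return out


def compute_sta(spikes, sequences: dict, frame_rate: float,
                window: float = 1.0, seed: int = 0,
                n_shuffles: int = 20) -> dict:
    """Spike-triggered average of each contrast sequence.

    ``spikes`` is a list of TrialSpikes (or one); ``sequences`` maps opsin
    name to the per-frame contrast array. The shuffled floor redraws spike
    times uniformly over the sequence duration. Returns
    ``{opsin: STAResult}``.
    """
    if not isinstance(spikes, (list, tuple)):
        spikes = [spikes]
    times = np.concatenate([ts.times for ts in spikes]) if spikes else np.empty(0)
    n_lags = int(round(window * frame_rate))
    lags = np.arange(n_lags) / frame_rate
    rng = np.random.default_rng(seed)

    results = {}
    for opsin, seq in sequences.items():
        seq = np.asarray(seq, float)
        duration = len(seq) / frame_rate
        valid_times = times[(times >= 0) & (times < duration)]
        if valid_times.size == 0:
            results[opsin] = STAResult(opsin, lags, np.zeros(n_lags), 0.0,
                                       "ON", 0.0, 0, empty=True)
            continue
        frame_idx = np.minimum((valid_times * frame_rate).astype(int),
                               len(seq) - 1)
        trace = _sta_matrix(seq, frame_idx, n_lags)
        amplitude = float(trace.max() - trace.min())

        floor_amps = np.empty(n_shuffles)
        for s in range(n_shuffles):
            fake = rng.integers(0, len(seq), size=valid_times.size)
            ftrace = _sta_matrix(seq, fake, n_lags)
            floor_amps[s] = ftrace.max() - ftrace.min()

        near = lags <= POLARITY_WINDOW_S + 1e-9
        dev = trace[near]
        i = int(np.argmax(np.abs(dev)))
        polarity = "ON" if dev[i] > 0 else "OFF"
        results[opsin] = STAResult(opsin, lags, trace, amplitude, polarity,
                                   float(floor_amps.mean()),
                                   int(valid_times.size))
    return results


def sta_to_frame(results: dict, unit_id=None):
    """Long-format DataFrame (unit_id, opsin, lag_s, mean_contrast)."""
    import pandas as pd
    rows = []
    for opsin, r in results.items():
        for lag, v in zip(r.lags, r.trace):
            rows.append((unit_id, opsin, lag, v))
    return pd.DataFrame(rows, columns=["unit_id", "opsin", "lag_s",
                                       "mean_contrast"])
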
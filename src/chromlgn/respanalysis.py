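"""Full-field response quantification and opponency / MR classification.

Cycle histograms (100 bins, 5-bin circular boxcar), peak-trough amplitudes
tested against a per-trial time-shuffle null, opponency calls from the
signs of cone-isolating responses (with an L-S vs L+S t-test fallback),
cone preference indices, a chi-square periodogram and melanopsin-response
classification from high/low step pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import ttest_ind

__all__ = [
    "CycleHistogram",
    "ResponseMeasure",
    "OpponencyCall",
    "MRCall",
    "ContrastCurve",
    "PeriodogramResult",
    "cycle_histogram",
    "response_amplitude",
    "classify_opponency",
    "cone_preference",
    "chi2_periodogram",
    "classify_mr",
]

N_BINS = 100
BOXCAR = 5


@dataclass
class CycleHistogram:
    """Mean firing rate per cycle phase bin, raw and boxcar-smoothed."""

    rates: np.ndarray
    smoothed: np.ndarray
    period: float

    def __post_init__(self):
        if len(self.rates) != N_BINS:
            raise ValueError(f"cycle histogram must have {N_BINS} bins")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


@dataclass
class ResponseMeasure:
    raw_amplitude: float
    shuffle_mean: float
    shuffle_limit95: float
    corrected_amplitude: float
    significant: bool
    polarity: str                     # "ON" or "OFF"
    signed_amplitude: float
    histogram: CycleHistogram | None = None


@dataclass
class OpponencyCall:
    label: str                        # non_opponent / L_ON_S_OFF / S_ON_L_OFF / non_responsive
    evidence: str                     # opposite_signs / LminusS_dominance / ...
    details: dict = field(default_factory=dict)


@dataclass
class MRCall:
    label: str                        # "MR" or "non_MR"
    per_intensity: dict = field(default_factory=dict)


@dataclass
class ContrastCurve:
    """Signed response amplitude vs contrast for one stimulus type."""

    contrasts: np.ndarray
    amplitudes: np.ndarray
    stimulus: str

    def __post_init__(self):
        c = np.asarray(self.contrasts, float)
        if np.any(np.diff(c) <= 0):
            raise ValueError("contrast levels must be ascending")
        self.contrasts = c


@dataclass
class PeriodogramResult:
    percent_variance: float

    def __post_init__(self):
        if not (-1e-9 <= self.percent_variance <= 100 + 1e-9):
            raise ValueError("percent variance must lie in [0, 100]")


def _gather(spikes):
    """(times, trial_index, total_duration) from a list of TrialSpikes."""
    times = [ts.times for ts in spikes]
    idx = np.concatenate([np.full(len(t), i) for i, t in enumerate(times)]) \
        if times else np.empty(0, int)
    tt = np.concatenate(times) if times else np.empty(0)
    durations = np.array([ts.duration for ts in spikes], dtype=float)
    if np.any(~np.isfinite(durations)):
        raise ValueError("trial durations must be finite for folding")
    return tt, idx.astype(int), durations


def _fold_rates(times, period, total_time):
    counts = np.bincount(
        np.floor((times % period) / period * N_BINS).astype(int) % N_BINS,
        minlength=N_BINS)
    return counts / (total_time / N_BINS)


def cycle_histogram(spikes: list, period: float) -> CycleHistogram:
    """Fold trials at the stimulus period into a 100-bin rate histogram."""
    if period <= 0:
        raise ValueError("period must be positive")
    if len(spikes) == 0:
        raise ValueError("need at least one trial")
    tt, _, durations = _gather(spikes)
    total = durations.sum()
    rates = _fold_rates(tt, period, total)
    smoothed = uniform_filter1d(rates, BOXCAR, mode="wrap")
    return CycleHistogram(rates, smoothed, period)


def _polarity(smoothed: np.ndarray) -> str:
    dev = smoothed - smoothed.mean()
    i = int(np.argmax(np.abs(dev)))
    in_bright = i < N_BINS // 2
    return "ON" if (dev[i] > 0) == in_bright else "OFF"


def response_amplitude(spikes: list, period: float, n_shuffles: int = 100,
                       seed: int = 0) -> ResponseMeasure:
    """Shuffle-corrected peak-trough amplitude of the smoothed cycle histogram.

    The null shuffles spike times independently per trial (circular shift by
    a uniform offset, preserving ISI structure); a unit is significant when
    its raw amplitude exceeds the 95th percentile of the null amplitudes,
    and the mean null amplitude is subtracted either way.
    """
    if n_shuffles < 20:
        warnings.warn("n_shuffles < 20 gives an unstable 95% limit")
    hist = cycle_histogram(spikes, period)
    raw = float(hist.smoothed.max() - hist.smoothed.min())

    tt, idx, durations = _gather(spikes)
    total = durations.sum()
    rng = np.random.default_rng(seed)
    offsets = rng.random((n_shuffles, len(spikes))) * durations[None, :]
    if tt.size:
        shifted = (tt[None, :] + offsets[:, idx]) % durations[idx][None, :]
        bins = np.floor((shifted % period) / period * N_BINS).astype(int) % N_BINS
        flat = bins + N_BINS * np.arange(n_shuffles)[:, None]
        counts = np.bincount(flat.ravel(), minlength=n_shuffles * N_BINS)
        null_rates = counts.reshape(n_shuffles, N_BINS) / (total / N_BINS)
    else:
        null_rates = np.zeros((n_shuffles, N_BINS))
    null_sm = uniform_filter1d(null_rates, BOXCAR, axis=1, mode="wrap")
    null_amps = null_sm.max(axis=1) - null_sm.min(axis=1)

    shuffle_mean = float(null_amps.mean())
    limit95 = float(np.percentile(null_amps, 95))
    corrected = raw - shuffle_mean
    significant = bool(raw > limit95)
    polarity = _polarity(hist.smoothed)
    signed = corrected if polarity == "ON" else -corrected
    return ResponseMeasure(raw, shuffle_mean, limit95, corrected, significant,
                           polarity, signed, hist)


def classify_opponency(L_measure: ResponseMeasure, S_measure: ResponseMeasure,
                       LminusS_amp: float, LplusS_amp: float,
                       trialwise_amplitudes: dict | None = None,
                       alpha: float = 0.05) -> OpponencyCall:
    """Opponency call from cone-isolating responses.

    Opposite-sign significant L and S responses give an opponent call
    directly; if exactly one opsin is detectable, the cell is opponent when
    per-block L-S amplitudes significantly exceed L+S (Welch t-test).
    ``trialwise_amplitudes`` must then hold keys "L-S" and "L+S" with the
    per-block amplitude estimates.
    """
    for m in (L_measure, S_measure):
        if m is None:
            raise ValueError("both cone-isolating measures are required")
    L_sig, S_sig = L_measure.significant, S_measure.significant
    if L_sig and S_sig:
        if L_measure.polarity != S_measure.polarity:
            label = ("L_ON_S_OFF" if L_measure.polarity == "ON"
                     else "S_ON_L_OFF")
            return OpponencyCall(label, "opposite_signs")
        return OpponencyCall("non_opponent", "same_signs")
    if L_sig != S_sig:  # exactly one detectable
        if trialwise_amplitudes is None or \
                "L-S" not in trialwise_amplitudes or \
                "L+S" not in trialwise_amplitudes:
            raise ValueError("trialwise L-S and L+S amplitudes required when "
                             "only one opsin response is detectable")
        a_ms = np.asarray(trialwise_amplitudes["L-S"], float)
        a_ps = np.asarray(trialwise_amplitudes["L+S"], float)
        t, p = ttest_ind(a_ms, a_ps, equal_var=False)
        if a_ms.mean() > a_ps.mean() and p < alpha:
            det, pol = (("L", L_measure.polarity) if L_sig
                        else ("S", S_measure.polarity))
            if det == "L":
                label = "L_ON_S_OFF" if pol == "ON" else "S_ON_L_OFF"
            else:
                label = "S_ON_L_OFF" if pol == "ON" else "L_ON_S_OFF"
            return OpponencyCall(label, "LminusS_dominance",
                                 {"t": float(t), "p": float(p)})
        return OpponencyCall("non_opponent", "single_opsin_no_dominance",
                             {"t": float(t), "p": float(p)})
    return OpponencyCall("non_responsive", "no_significant_response")


def cone_preference(L_R: float, S_R: float) -> float:
    """(L_R - S_R) / (L_R + S_R) over absolute response amplitudes."""
    if L_R < 0 or S_R < 0:
        raise ValueError("amplitudes must be nonnegative")
    if L_R + S_R == 0:
        raise ValueError("cone preference undefined when both amplitudes are 0")
    return (L_R - S_R) / (L_R + S_R)


def chi2_periodogram(series: np.ndarray, period_samples: int) -> PeriodogramResult:
    """Percent of series variance captured by the mean waveform at the period."""
    x = np.asarray(series, float)
    if period_samples < 1:
        raise ValueError("period must be at least one sample")
    n_cycles = len(x) // period_samples
    if n_cycles < 2:
        raise ValueError("series must cover at least 2 periods")
    n_keep = n_cycles * period_samples
    if n_keep != len(x):
        warnings.warn("series truncated to a whole number of cycles")
        x = x[:n_keep]
    folded = x.reshape(n_cycles, period_samples)
    cycle_mean = folded.mean(axis=0)
    total_var = x.var()
    if total_var == 0:
        return PeriodogramResult(0.0)
    rhythm_var = np.tile(cycle_mean, n_cycles).var()
    return PeriodogramResult(float(min(100.0 * rhythm_var / total_var, 100.0)))


def _window_rates(trains, lo: float, hi: float) -> np.ndarray:
    return np.array([np.count_nonzero((ts.times >= lo) & (ts.times < hi))
                     / (hi - lo) for ts in trains])


def classify_mr(step_responses: dict, pre_s: float = 10.0,
                step_s: float = 10.0, early_s: float = 0.25,
                late_s: float = 5.0, alpha: float = 0.05) -> MRCall:
    """Melanopsin-responsive call from high/low step pairs.

    ``step_responses`` maps intensity label to ``{"high": [TrialSpikes],
    "low": [...]}`` where time 0 is trial start and the step onsets at
    ``pre_s``. MR requires, at some intensity, a significantly greater
    late (last 5 s) baseline-subtracted rate for high than low while the
    early (first 250 ms) responses do not differ (Welch t-tests).
    """
    if pre_s <= 0:
        raise ValueError("a pre-stimulus baseline is required")
    per_intensity = {}
    is_mr = False
    for intensity, pair in step_responses.items():
        rates = {}
        for cond in ("high", "low"):
            trains = pair[cond]
            if len(trains) < 2:
                raise ValueError("need >= 2 trials per condition")
            base = _window_rates(trains, 0.0, pre_s)
            early = _window_rates(trains, pre_s, pre_s + early_s) - base
            late = _window_rates(trains, pre_s + step_s - late_s,
                                 pre_s + step_s) - base
            rates[cond] = {"early": early, "late": late}
        t_l, p_late = ttest_ind(rates["high"]["late"], rates["low"]["late"],
                                equal_var=False)
        t_e, p_early = ttest_ind(rates["high"]["early"], rates["low"]["early"],
                                 equal_var=False)
        if np.isnan(p_late):
            p_late = 1.0
        if np.isnan(p_early):  # identical early responses: not different
            p_early = 1.0
        late_greater = rates["high"]["late"].mean() > rates["low"]["late"].mean()
        qualifies = bool(late_greater and p_late < alpha and p_early >= alpha)
        per_intensity[intensity] = {
            "early_high": float(rates["high"]["early"].mean()),
            "early_low": float(rates["low"]["early"].mean()),
            "late_high": float(rates["high"]["late"].mean()),
            "late_low": float(rates["low"]["late"].mean()),
            "p_late": float(p_late), "p_early": float(p_early),
            "qualifies": qualifies,
        }
        is_mr = is_mr or qualifies
    return MRCall("MR" if is_mr else "non_MR", per_intensity)
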
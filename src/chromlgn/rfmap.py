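"""Receptive-field mapping from bar/square stimuli and derived statistics.

Builds location-response maps from peri-event firing (peak 50 ms epoch in
the 35-125 ms post-onset window against a 100 ms pre-onset baseline), fits
1-D or 2-D Gaussians to estimate RF centers, types opponency from paired
L/S maps, and tests cone-preference trends against RF elevation/azimuth
with an extra sum-of-squares F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

__all__ = [
    "LocationResponseMap",
    "RFEstimate",
    "RFOpponencyCall",
    "ElevationTrend",
    "RETINAL_MIDPOINT_ELEVATION_DEG",
    "location_response_map",
    "fit_rf_center",
    "classify_rf_opponency",
    "elevation_trend",
]

#: Elevation (deg, snout-relative) of the projected dorsal-ventral retinal
#: midpoint; stored once as the coordinate-convention anchor.
RETINAL_MIDPOINT_ELEVATION_DEG = 22.0

RESPONSE_WINDOW = (0.035, 0.125)   # s post-onset searched for the peak epoch
PEAK_EPOCH = 0.050                 # s
EPOCH_STEP = 0.005                 # s
BASELINE_WINDOW = 0.100            # s pre-onset

#: minimum fraction of variance a Gaussian fit must explain to accept an RF
DEFAULT_VE_THRESHOLD = 0.4


@dataclass
class LocationResponseMap:
    """Responses (spikes/s change) per tested location and polarity."""

    azimuths: np.ndarray           # sorted unique grid values
    elevations: np.ndarray
    light: np.ndarray              # (n_elev, n_az); NaN where untested
    dark: np.ndarray
    combined: np.ndarray
    cell_type: str                 # "ON", "OFF" or "ON_OFF"

    def axis_profile(self, axis: str) -> tuple:
        """Collapse the combined map to 1-D by nanmean over the other axis."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if axis == "azimuth":
                return self.azimuths, np.nanmean(self.combined, axis=0)
            if axis == "elevation":
                return self.elevations, np.nanmean(self.combined, axis=1)
        raise ValueError("axis must be 'azimuth' or 'elevation'")


@dataclass
class RFEstimate:
    center: tuple                  # (azimuth, elevation); 1-D fits fill one
    sigma: float                   # deg
    variance_explained: float
    kind: str                      # "1D" or "2D"
    amplitude: float = 0.0
    accepted: bool = True


@dataclass
class RFOpponencyCall:
    label: str
    overlap: float = np.nan        # center distance / mean sigma
    details: dict = field(default_factory=dict)


@dataclass
class ElevationTrend:
    axis: str
    bin_centers: np.ndarray
    bin_means: np.ndarray
    slope: float
    intercept: float
    F: float
    p_value: float


def _event_response(trains, onsets, bin_s: float = EPOCH_STEP) -> float:
    """Peak 50 ms epoch rate in the search window minus pre-onset baseline.

    ``trains`` maps trial -> spike-time array; ``onsets`` is a list of
    (trial, onset_s) for one stimulus condition.
    """
    lo, hi = RESPONSE_WINDOW
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    n_bins = len(edges) - 1
    psth = np.zeros(n_bins)
    base_count = 0.0
    n = 0
    for trial, onset in onsets:
        t = trains.get(trial)
        if t is None:
            continue
        rel = t - onset
        psth += np.histogram(rel, bins=edges)[0]
        base_count += np.count_nonzero((rel >= -BASELINE_WINDOW) & (rel < 0))
        n += 1
    if n == 0:
        return np.nan
    psth_rate = psth / (n * bin_s)
    base_rate = base_count / (n * BASELINE_WINDOW)
    k = int(round(PEAK_EPOCH / bin_s))
    if k >= n_bins:
        window_rates = [psth_rate.mean()]
    else:
        window_rates = np.convolve(psth_rate, np.ones(k) / k, mode="valid")
    return float(np.max(window_rates) - base_rate)


def location_response_map(spikes: list, events: list,
                          cell_type: str = "auto") -> LocationResponseMap:
    """Per-location light/dark responses combined per the cell's type.

    ``spikes`` is a list of TrialSpikes; ``events`` of SpatialEvent (one
    opsin channel at a time). Light and dark maps are subtracted for ON or
    OFF cells and added for ON-OFF cells; with ``cell_type="auto"`` the
    dominant sign of the light-dark difference decides ON vs OFF.
    """
    trains = {ts.trial: ts.times for ts in spikes}
    azimuths = np.array(sorted({ev.azimuth for ev in events}))
    elevations = np.array(sorted({ev.elevation for ev in events}))
    shape = (len(elevations), len(azimuths))
    maps = {1: np.full(shape, np.nan), -1: np.full(shape, np.nan)}
    az_i = {a: i for i, a in enumerate(azimuths)}
    el_i = {e: i for i, e in enumerate(elevations)}
    for pol in (1, -1):
        conds = {}
        for ev in events:
            if ev.polarity != pol:
                continue
            conds.setdefault((ev.azimuth, ev.elevation), []).append(
                (ev.trial, ev.onset))
        for (az, el), onsets in conds.items():
            maps[pol][el_i[el], az_i[az]] = _event_response(trains, onsets)

    light, dark = maps[1], maps[-1]
    if cell_type == "auto":
        diff = light - dark
        peak = np.nanmax(np.abs(diff)) if np.isfinite(diff).any() else 0.0
        if peak == 0:
            cell_type = "ON"
        else:
            i = np.nanargmax(np.abs(diff))
            cell_type = "ON" if diff.ravel()[i] > 0 else "OFF"
    if cell_type == "ON":
        combined = light - dark
    elif cell_type == "OFF":
        combined = dark - light
    elif cell_type == "ON_OFF":
        combined = light + dark
    else:
        raise ValueError(f"unknown cell type {cell_type!r}")
    return LocationResponseMap(azimuths, elevations, light, dark, combined,
                               cell_type)


def _gauss1d(x, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def fit_rf_center(resp_map: LocationResponseMap, kind: str = "2D",
                  axis: str = "azimuth",
                  ve_threshold: float = DEFAULT_VE_THRESHOLD) -> RFEstimate:
    """Least-squares Gaussian (+offset) fit of the combined response map."""
    if kind == "1D":
        x, y = resp_map.axis_profile(axis)
        ok = np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 5:
            raise ValueError("need >= 5 locations along the fitted axis")
        p0 = [y.max() - y.min(), x[np.argmax(y)], (x[-1] - x[0]) / 6,
              float(np.median(y))]
        try:
            popt, _ = curve_fit(_gauss1d, x, y, p0=p0, maxfev=5000)
        except RuntimeError:
            return RFEstimate((np.nan, np.nan), np.nan, 0.0, "1D",
                              accepted=False)
        pred = _gauss1d(x, *popt)
        ve = _variance_explained(y, pred)
        center = ((popt[1], np.nan) if axis == "azimuth"
                  else (np.nan, popt[1]))
        return RFEstimate(center, abs(popt[2]), ve, "1D", popt[0],
                          accepted=_accept(popt[1], x, ve, ve_threshold))
    if kind != "2D":
        raise ValueError("kind must be '1D' or '2D'")

    A, E = np.meshgrid(resp_map.azimuths, resp_map.elevations)
    Z = resp_map.combined
    ok = np.isfinite(Z)
    if resp_map.azimuths.size < 5 or resp_map.elevations.size < 5:
        raise ValueError("need >= 5 locations along each fitted axis")
    a, e, z = A[ok], E[ok], Z[ok]

    def g2(xy, amp, mux, muy, sigma, offset):
        xa, xe = xy
        return amp * np.exp(-((xa - mux) ** 2 + (xe - muy) ** 2)
                            / (2 * sigma ** 2)) + offset

    imax = np.argmax(z)
    p0 = [z.max() - z.min(), a[imax], e[imax],
          (resp_map.azimuths[-1] - resp_map.azimuths[0]) / 6,
          float(np.median(z))]
    try:
        popt, _ = curve_fit(g2, (a, e), z, p0=p0, maxfev=8000)
    except RuntimeError:
        return RFEstimate((np.nan, np.nan), np.nan, 0.0, "2D", accepted=False)
    ve = _variance_explained(z, g2((a, e), *popt))
    in_x = _within(popt[1], resp_map.azimuths)
    in_y = _within(popt[2], resp_map.elevations)
    return RFEstimate((float(popt[1]), float(popt[2])), abs(float(popt[3])),
                      ve, "2D", float(popt[0]),
                      accepted=bool(ve >= ve_threshold and in_x and in_y))


def _variance_explained(y, pred) -> float:
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0


def _within(mu, grid) -> bool:
    pad = (grid[-1] - grid[0]) / max(len(grid) - 1, 1)
    return grid[0] - pad <= mu <= grid[-1] + pad


def _accept(mu, x, ve, thresh) -> bool:
    return bool(ve >= thresh and _within(mu, x))


def classify_rf_opponency(L_fit: RFEstimate | None, S_fit: RFEstimate | None,
                          L_amp: float, S_amp: float,
                          fullfield_call=None) -> RFOpponencyCall:
    """Type a cell from its per-opsin RF fits and full-field opponency call.

    ``L_amp``/``S_amp`` are the signed center response amplitudes (positive
    = ON). A cell with both RFs mapped and opposite center polarity is RF
    opponent; same polarity or a single mappable RF falls back on the
    full-field call.
    """
    L_ok = L_fit is not None and L_fit.accepted
    S_ok = S_fit is not None and S_fit.accepted
    ff_label = getattr(fullfield_call, "label", None)
    ff_opponent = ff_label in ("L_ON_S_OFF", "S_ON_L_OFF")
    if L_ok and S_ok:
        dist = float(np.hypot(L_fit.center[0] - S_fit.center[0],
                              L_fit.center[1] - S_fit.center[1]))
        overlap = dist / ((L_fit.sigma + S_fit.sigma) / 2)
        if np.sign(L_amp) != np.sign(S_amp) and L_amp != 0 and S_amp != 0:
            label = ("opponent_RF_L_ON_S_OFF" if L_amp > 0
                     else "opponent_RF_S_ON_L_OFF")
            return RFOpponencyCall(label, overlap)
        if ff_opponent:
            return RFOpponencyCall("fullfield_only_opponent", overlap,
                                   {"fullfield": ff_label})
        return RFOpponencyCall("non_opponent", overlap)
    if L_ok or S_ok:
        if ff_opponent:
            return RFOpponencyCall("fullfield_only_opponent",
                                   details={"fullfield": ff_label})
        return RFOpponencyCall("single_opsin_only")
    if ff_opponent:
        return RFOpponencyCall("fullfield_only_opponent",
                               details={"fullfield": ff_label})
    if ff_label is None:
        raise ValueError("nothing mappable and no full-field call")
    return RFOpponencyCall("non_opponent" if ff_label == "non_opponent"
                           else "unclassifiable")


def _trend(position: np.ndarray, preference: np.ndarray, axis: str,
           bin_width: float) -> ElevationTrend:
    lo = np.floor(position.min() / bin_width) * bin_width
    hi = np.ceil(position.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(position, edges) - 1, 0, len(edges) - 2)
    centers, means = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            centers.append((edges[b] + edges[b + 1]) / 2)
            means.append(preference[sel].mean())
    centers, means = np.array(centers), np.array(means)
    k = len(centers)
    if k < 3:
        raise ValueError("need >= 3 populated bins for a trend")
    slope, intercept = np.polyfit(centers, means, 1)
    ss_line = np.sum((means - (slope * centers + intercept)) ** 2)
    ss_const = np.sum((means - means.mean()) ** 2)
    if ss_line <= 1e-300 * max(ss_const, 1.0):
        F = np.finfo(float).max if ss_const > ss_line else 0.0
        p = 0.0 if F > 0 else 1.0
    else:
        F = max(((ss_const - ss_line) / 1.0) / (ss_line / (k - 2)), 0.0)
        p = float(f_dist.sf(F, 1, k - 2))
    return ElevationTrend(axis, centers, means, float(slope),
                          float(intercept), float(F), p)


def elevation_trend(cells: list, bin_width: float = 10.0) -> dict:
    """Binned cone preference vs RF elevation and azimuth, with F-tests.

    ``cells`` holds (preference, elevation_deg, azimuth_deg) tuples.
    Returns ``{"elevation": ElevationTrend, "azimuth": ElevationTrend}``.
    """
    arr = np.asarray(cells, float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("cells must be (preference, elevation, azimuth) rows")
    pref, elev, azim = arr[:, 0], arr[:, 1], arr[:, 2]
    return {"elevation": _trend(elev, pref, "elevation", bin_width),
            "azimuth": _trend(azim, pref, "azimuth", bin_width)}
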
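"""Random-wiring retinal model: center-surround sampling of a graded mosaic.

Simulates 1-D strips of the dorsal-ventral retina populated by S-only,
L-only and co-expressing cones whose S-opsin fraction follows a parametric
gradient, then asks whether a non-selective center-surround receptive
field sampling that mosaic produces opposite-signed responses to L- and
S-opsin-isolating stimuli, as a function of surround weight, RF size,
sampling fraction and retinal position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "ConeGradient",
    "RetinalStrip",
    "ModelRFSpec",
    "ModelResult",
    "sample_strip",
    "rf_response",
    "sweep",
]

#: |response| below this fraction of the larger opsin response is treated
#: as zero when calling opponency
OPPONENCY_TOL = 1e-6

#: minimum |response| (effective contrast units) for an opsin response to
#: count as detectable; without it the surround_weight = 1 case is
#: degenerate (center/surround means cancel antisymmetrically, so any
#: nonzero mosaic fluctuation would read as opponent)
DETECTION_THRESHOLD = 0.005


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ConeGradient:
    """Parametric stand-in for the dorsal-ventral cone-opsin gradient.

    Position runs 0 (dorsal pole) to 1 (ventral pole) with the retinal
    midpoint at 0.5. Co-expressing cones dominate; their per-cone S-opsin
    fraction rises from ``s_min`` dorsally to ``s_max`` ventrally along a
    logistic centred at ``s_mid`` (slightly dorsal of the midpoint, so the
    steep part of the gradient sits in dorsal retina). L-only cones taper
    off ventrally and a sparse S-only population appears far ventrally.
    """

    s_min: float = 0.1
    s_max: float = 0.9
    s_mid: float = 0.45
    s_width: float = 0.12
    l_only_peak: float = 0.10
    l_only_mid: float = 0.40
    s_only_peak: float = 0.05
    s_only_mid: float = 0.75

    def __post_init__(self):
        if not (0.0 <= self.s_min < self.s_max <= 1.0):
            raise ValueError("need 0 <= s_min < s_max <= 1")

    def s_fraction(self, u: np.ndarray) -> np.ndarray:
        """Co-expresser S-opsin fraction at position u."""
        return self.s_min + (self.s_max - self.s_min) * _sigmoid(
            (np.asarray(u, float) - self.s_mid) / self.s_width)

    def type_probs(self, u: np.ndarray) -> np.ndarray:
        """(n, 3) probabilities of [S_only, L_only, coexpressing] at u."""
        u = np.atleast_1d(np.asarray(u, float))
        p_l = self.l_only_peak * (1.0 - _sigmoid((u - self.l_only_mid) / 0.08))
        p_s = self.s_only_peak * _sigmoid((u - self.s_only_mid) / 0.08)
        p_co = 1.0 - p_l - p_s
        probs = np.stack([p_s, p_l, p_co], axis=1)
        if np.any(probs < 0):
            raise ValueError("degenerate gradient: negative type probability")
        return probs


CONE_TYPES = ("S_only", "L_only", "coexpressing")


@dataclass
class RetinalStrip:
    """Sampled cones along one dorsal-ventral strip."""

    positions: np.ndarray          # in [0, 1], sorted
    types: np.ndarray              # index into CONE_TYPES
    s_fractions: np.ndarray        # per-cone S-opsin fraction
    seed: int
    extent_deg: float = 100.0      # visual angle spanned by the strip

    def __len__(self):
        return len(self.positions)

    def positions_deg(self) -> np.ndarray:
        return self.positions * self.extent_deg


def sample_strip(gradient: ConeGradient, n_cones: int = 800,
                 seed: int = 0, extent_deg: float = 100.0) -> RetinalStrip:
    """Draw cone positions uniformly and types from the gradient."""
    if n_cones < 1:
        raise ValueError("n_cones must be >= 1")
    rng = np.random.default_rng(seed)
    u = np.sort(rng.random(n_cones))
    probs = gradient.type_probs(u)
    if np.allclose(probs.sum(), 0.0):
        raise ValueError("degenerate gradient: all densities zero")
    cdf = np.cumsum(probs, axis=1)
    r = rng.random(n_cones)
    types = (r[:, None] > cdf).sum(axis=1)
    s_frac = np.where(types == 0, 1.0,
                      np.where(types == 1, 0.0, gradient.s_fraction(u)))
    return RetinalStrip(u, types, s_frac, seed, extent_deg)


@dataclass(frozen=True)
class ModelRFSpec:
    """Center-surround RF parameters; surround diameter is fixed at 3x."""

    center_deg: float              # position along the strip, degrees
    center_diameter: float         # 6-20 deg
    surround_weight: float         # 0.5-1 in the sweep; 0 allowed for checks
    sampling_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling fraction must be in (0, 1]")
        if self.surround_weight < 0:
            raise ValueError("surround weight must be nonnegative")
        if self.center_diameter <= 0:
            raise ValueError("center diameter must be positive")

    @property
    def surround_diameter(self) -> float:
        return 3.0 * self.center_diameter


@dataclass
class ModelResult:
    response_L: float
    response_S: float
    opponent: bool
    bias: float                    # (|L| - |S|) / (|L| + |S|)
    dv_position: float             # center position in [0, 1]
    rf: ModelRFSpec
    empty: bool = False


def rf_response(strip: RetinalStrip, rf: ModelRFSpec,
                stimulus: dict | None = None,
                seed: int = 0,
                detection_threshold: float = DETECTION_THRESHOLD) -> ModelResult:
    """Center-minus-surround opsin responses of one RF on one strip.

    Each opsin's response is the Gaussian-weighted mean opsin fraction over
    the sampled center cones minus ``surround_weight`` times that over the
    (independently sampled) surround cones, scaled by the stimulus contrast
    for that opsin. Opponency = opposite signs, both above tolerance.
    """
    stimulus = stimulus or {"L": 0.75, "S": 0.75}
    pos = strip.positions_deg()
    if not (pos.min() <= rf.center_deg <= pos.max()):
        raise ValueError("RF center outside the strip extent")
    sigma_c = rf.center_diameter / 4.0
    sigma_s = rf.surround_diameter / 4.0
    rng = np.random.default_rng(seed)

    d2 = (pos - rf.center_deg) ** 2
    resp = {}
    for sigma, key in ((sigma_c, "c"), (sigma_s, "s")):
        w = np.exp(-d2 / (2 * sigma ** 2))
        if rf.sampling_fraction < 1.0:
            w = w * (rng.random(len(w)) < rf.sampling_fraction)
        tot = w.sum()
        if tot <= 0:
            return ModelResult(0.0, 0.0, False, 0.0,
                               rf.center_deg / strip.extent_deg, rf,
                               empty=True)
        resp[key + "_S"] = float(w @ strip.s_fractions) / tot
        resp[key + "_L"] = float(w @ (1.0 - strip.s_fractions)) / tot

    r_L = stimulus["L"] * (resp["c_L"] - rf.surround_weight * resp["s_L"])
    r_S = stimulus["S"] * (resp["c_S"] - rf.surround_weight * resp["s_S"])
    tol = max(OPPONENCY_TOL * max(abs(r_L), abs(r_S), 1e-300),
              detection_threshold)
    opponent = bool(abs(r_L) > tol and abs(r_S) > tol
                    and np.sign(r_L) != np.sign(r_S))
    denom = abs(r_L) + abs(r_S)
    bias = (abs(r_L) - abs(r_S)) / denom if denom > 0 else 0.0
    return ModelResult(float(r_L), float(r_S), opponent, float(bias),
                       rf.center_deg / strip.extent_deg, rf)


def sweep(gradient: ConeGradient, diameters=(6.0, 12.0, 20.0),
          surround_weights=(0.5, 0.75, 0.9, 1.0),
          sampling_fractions=(0.5, 1.0), n_strips: int = 100,
          n_cones: int = 800, n_centers: int = 21, seed: int = 0,
          center_margin: float = 0.15) -> "pandas.DataFrame":
    """Opponency prevalence over the parameter grid, 100 strips per model.

    RF centers are placed evenly along the central portion of each strip
    (margins avoid edge effects). The same strips and center positions are
    reused across parameter cells (common random numbers), so prevalence
    differences across cells are not sampling artifacts. Returns a tidy
    DataFrame with one row per (parameter cell x strip x center).
    """
    import pandas as pd
    strips = [sample_strip(gradient, n_cones, seed + i) for i in range(n_strips)]
    extent = strips[0].extent_deg
    centers = np.linspace(center_margin, 1.0 - center_margin, n_centers) * extent
    rows = []
    for diam, sw, frac in product(diameters, surround_weights,
                                  sampling_fractions):
        for si, strip in enumerate(strips):
            for ci, c in enumerate(centers):
                rf = ModelRFSpec(c, diam, sw, frac)
                res = rf_response(strip, rf, seed=seed + 1000 * si + ci)
                rows.append({
                    "diameter": diam, "surround_weight": sw,
                    "sampling_fraction": frac, "strip": si,
                    "dv_position": res.dv_position,
                    "response_L": res.response_L,
                    "response_S": res.response_S,
                    "opponent": res.opponent, "bias": res.bias,
                })
    return pd.DataFrame(rows)


def summarize_sweep(df) -> "pandas.DataFrame":
    """Per parameter cell: prevalence, dorsal/ventral split, bias contrast."""
    def agg(g):
        dorsal = g[g.dv_position < 0.5]
        ventral = g[g.dv_position >= 0.5]
        opp = g[g.opponent]
        non = g[~g.opponent]
        return {
            "prevalence": g.opponent.mean(),
            "prevalence_dorsal": dorsal.opponent.mean() if len(dorsal) else np.nan,
            "prevalence_ventral": ventral.opponent.mean() if len(ventral) else np.nan,
            "mean_abs_bias_opponent": opp.bias.abs().mean() if len(opp) else np.nan,
            "mean_abs_bias_non_opponent": non.bias.abs().mean() if len(non) else np.nan,
            "n": len(g),
        }
    import pandas as pd
    keys = ["diameter", "surround_weight", "sampling_fraction"]
    out = df.groupby(keys).apply(lambda g: pd.Series(agg(g)),
                                 include_groups=False)
    return out.reset_index()
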
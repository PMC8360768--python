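"""Multiprimary silent-substitution design and stimulus waveform synthesis.

Solves per-primary modulations around a background so that opsin-effective
flux changes hit requested Michelson contrasts (with other opsins silenced
or minimized), validates the result by recomputing contrasts from the full
emitted spectra, and builds square-wave, step and white-noise waveforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import minimize, minimize_scalar

from .photoreceptors import (
    LensFilter,
    Opsin,
    SpectralCurve,
    WavelengthGrid,
    default_grid,
    default_lens,
    effective_flux,
    michelson_contrast,
    nomogram_sensitivity,
)

__all__ = [
    "OPSINS",
    "Primary",
    "Background",
    "ContrastSpec",
    "SubstitutionSolution",
    "Waveform",
    "gaussian_primary",
    "default_primaries",
    "flux_matrix",
    "make_background",
    "solve_silent_substitution",
    "validate_solution",
    "build_square_wave",
    "build_step_pair",
    "build_white_noise",
]

#: Canonical opsin ordering used for all matrices and contrast vectors.
OPSINS = ("S", "L", "rod", "mel")


@dataclass(frozen=True)
class Primary:
    """A spectral primary (LED) described by its unit-drive spectrum."""

    label: str
    spectrum: SpectralCurve
    max_drive: float = np.inf

    def __post_init__(self):
        if self.max_drive <= 0:
            raise ValueError("max_drive must be positive")


def gaussian_primary(label: str, peak_nm: float, fwhm_nm: float = 20.0,
                     grid: WavelengthGrid | None = None,
                     max_drive: float = np.inf) -> Primary:
    """Gaussian LED model: unit peak spectral flux density at ``peak_nm``."""
    grid = grid or default_grid()
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((grid.wavelengths - peak_nm) / sigma) ** 2)
    return Primary(label, SpectralCurve(grid, vals), max_drive)


def default_primaries(grid: WavelengthGrid | None = None,
                      peaks=(405.0, 460.0, 620.0),
                      fwhm_nm: float = 20.0) -> list[Primary]:
    grid = grid or default_grid()
    return [gaussian_primary(f"{int(p)}nm", p, fwhm_nm, grid) for p in peaks]


def flux_matrix(primaries: list[Primary], lens: LensFilter | None = None,
                opsins=OPSINS) -> np.ndarray:
    """Matrix M[o, p]: opsin-effective flux of primary p at unit drive."""
    lens = lens if lens is not None else default_lens(primaries[0].spectrum.grid)
    M = np.empty((len(opsins), len(primaries)))
    for i, name in enumerate(opsins):
        sens = nomogram_sensitivity(Opsin(name), primaries[0].spectrum.grid)
        for j, prim in enumerate(primaries):
            M[i, j] = effective_flux(prim.spectrum, sens, lens)
    return M


@dataclass(frozen=True)
class Background:
    """Steady multiprimary background: per-primary drives plus derived fluxes."""

    drives: np.ndarray
    fluxes: dict  # opsin -> effective flux at nd_level 0
    nd_level: int = 0
    variant: str = "daylight-matched"

    def __post_init__(self):
        d = np.asarray(self.drives, dtype=float)
        if np.any(d < 0):
            raise ValueError("background drives must be nonnegative")
        if not 0 <= int(self.nd_level) <= 4:
            raise ValueError("nd_level must be an integer in 0..4")
        object.__setattr__(self, "drives", d)

    @property
    def nd_scale(self) -> float:
        """Spectrally neutral attenuation factor 10**-nd."""
        return 10.0 ** (-self.nd_level)

    def with_nd(self, nd_level: int) -> "Background":
        return Background(self.drives, self.fluxes, nd_level, self.variant)


#: Target flux ratios (S : L : rod) used to construct backgrounds. Ratios
#: are tuned so the full stimulus battery stays inside the LED gamut: the
#: daylight-matched variant supports 75% cone-isolating and 45%
#: rod-isolating modulations with small rod/mel residuals; the reduced-S
#: variant additionally supports joint +-65% rod/L/S noise (independent
#: rod and cone contrast needs much lower S irradiance).
_BACKGROUND_RATIOS = {
    "daylight-matched": (0.15, 1.0, 0.42),
    "reduced-S": (0.05, 1.0, 0.40),
}


def make_background(primaries: list[Primary], variant: str = "daylight-matched",
                    lens: LensFilter | None = None, nd_level: int = 0,
                    scale: float = 1.0) -> Background:
    """Solve per-primary drives producing the variant's S:L:rod flux ratios.

    Drives are normalized so the largest equals ``scale``.
    """
    if variant not in _BACKGROUND_RATIOS:
        raise ValueError(f"unknown background variant {variant!r}")
    if len(primaries) != 3:
        raise ValueError("background construction requires exactly 3 primaries")
    M = flux_matrix(primaries, lens)
    ratios = np.array(_BACKGROUND_RATIOS[variant])
    A = M[:3, :]  # S, L, rod rows
    d = np.linalg.solve(A, ratios)
    if np.any(d <= 0):
        raise ValueError(f"variant {variant!r} infeasible with these primaries: "
                         f"drives {d}")
    d = d / d.max() * scale
    fluxes = {name: float(f) for name, f in zip(OPSINS, M @ d)}
    return Background(d, fluxes, nd_level, variant)


@dataclass(frozen=True)
class ContrastSpec:
    """Per-opsin constraint roles for the substitution solver.

    ``entries`` maps opsin name to ``("target", value)``, ``("silenced", 0)``,
    ``("minimize", None)`` or ``("free", None)``. Unlisted opsins are free.
    """

    entries: dict

    def __post_init__(self):
        for name, (role, value) in self.entries.items():
            if name not in OPSINS:
                raise ValueError(f"unknown opsin {name!r}")
            if role not in ("target", "silenced", "minimize", "free"):
                raise ValueError(f"unknown role {role!r}")
            if role == "target" and not (abs(value) < 1):
                raise ValueError("target Michelson contrast must satisfy |c| < 1")

    @classmethod
    def isolate(cls, opsin: str, contrast: float, silence=(),
                minimize=()) -> "ContrastSpec":
        entries = {opsin: ("target", float(contrast))}
        for s in silence:
            entries[s] = ("silenced", 0.0)
        for m in minimize:
            entries[m] = ("minimize", None)
        return cls(entries)

    def constrained(self):
        out = []
        for name, (role, value) in self.entries.items():
            if role == "target":
                out.append((name, float(value)))
            elif role == "silenced":
                out.append((name, 0.0))
        return out

    def minimized(self):
        return [n for n, (r, _) in self.entries.items() if r == "minimize"]


@dataclass
class SubstitutionSolution:
    """Solver output: per-primary modulation plus achieved opsin contrasts."""

    modulation: np.ndarray          # delta_drive / background_drive, per primary
    delta_drives: np.ndarray        # absolute drive excursion, per primary
    achieved: dict                  # opsin -> Michelson contrast (from spectra)
    feasible: bool
    spec: ContrastSpec
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "modulation": list(map(float, self.modulation)),
            "delta_drives": list(map(float, self.delta_drives)),
            "achieved": {k: float(v) for k, v in self.achieved.items()},
            "feasible": bool(self.feasible),
            "constraints": {k: {"role": r, "value": v}
                            for k, (r, v) in self.spec.entries.items()},
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool))},
        }, indent=2)


def _achieved_contrasts(primaries, background, delta, lens):
    """Recompute per-opsin contrast from the full bright/dim spectra."""
    grid = primaries[0].spectrum.grid
    bright = np.zeros(len(grid))
    dim = np.zeros(len(grid))
    for p, db, dd in zip(primaries, background.drives + delta,
                         background.drives - delta):
        bright += db * p.spectrum.values
        dim += dd * p.spectrum.values
    lens = lens if lens is not None else default_lens(grid)
    out = {}
    for name in OPSINS:
        sens = nomogram_sensitivity(Opsin(name), grid)
        fb = effective_flux(SpectralCurve(grid, np.clip(bright, 0, None)), sens, lens)
        fd = effective_flux(SpectralCurve(grid, np.clip(dim, 0, None)), sens, lens)
        out[name] = michelson_contrast(fb, fd)
    return out


def solve_silent_substitution(primaries: list[Primary], background: Background,
                              spec: ContrastSpec, lens: LensFilter | None = None,
                              tol: float = 1e-6) -> SubstitutionSolution:
    """Solve per-primary modulations achieving the requested opsin contrasts.

    Constrained (target/silenced) opsins form a linear system in the drive
    excursions; any remaining degrees of freedom are used to minimize the
    maximum absolute contrast over the "minimize" opsins. Achieved contrasts
    are recomputed from the emitted spectra, not from the design matrix.
    """
    M = flux_matrix(primaries, lens)
    F0 = M @ background.drives
    constrained = spec.constrained()
    n_con, n_prim = len(constrained), len(primaries)
    if n_con > n_prim:
        raise ValueError("more constrained opsins than primaries")
    for name, _ in constrained:
        if F0[OPSINS.index(name)] <= 0:
            raise ValueError(f"background flux for constrained opsin {name} is zero")

    if n_con == 0:
        delta = np.zeros(n_prim)
    else:
        rows = [OPSINS.index(name) for name, _ in constrained]
        A = M[rows, :]
        rhs = np.array([c * F0[i] for (_, c), i in zip(constrained, rows)])
        cond = np.linalg.cond(A @ A.T)
        if cond > 1e12:
            raise ValueError(f"singular constraint system (condition {cond:.3g})")
        delta, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        if n_con < n_prim:
            N = null_space(A)
            min_rows = [OPSINS.index(n) for n in spec.minimized()]
            if min_rows and N.size:
                Mm = M[min_rows, :] / F0[min_rows, None]
                base = Mm @ delta          # contrast of minimized opsins at z=0
                G = Mm @ N                 # sensitivity to nullspace coords

                def objective(z):
                    return np.max(np.abs(base + G @ np.atleast_1d(z)))

                max_drives_ = np.array([p.max_drive for p in primaries])
                bound = np.minimum(background.drives,
                                   max_drives_ - background.drives)
                if N.shape[1] == 1:
                    # feasible interval for z from |delta0 + N z| <= bound
                    lo, hi = -np.inf, np.inf
                    for d0p, Np, bp in zip(delta, N[:, 0], bound):
                        if abs(Np) < 1e-15:
                            continue
                        a, b = (-bp - d0p) / Np, (bp - d0p) / Np
                        lo, hi = max(lo, min(a, b)), min(hi, max(a, b))
                    if lo > hi or not np.isfinite(lo) or not np.isfinite(hi):
                        span = float(np.max(np.abs(background.drives))) * 10 + 1
                        lo, hi = -span, span
                    res = minimize_scalar(lambda z: objective([z]),
                                          bounds=(lo, hi), method="bounded",
                                          options={"xatol": 1e-13})
                    delta = delta + N[:, 0] * res.x
                else:
                    res = minimize(objective, np.zeros(N.shape[1]),
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-12, "fatol": 1e-14})
                    delta = delta + N @ res.x

    bright = background.drives + delta
    dim = background.drives - delta
    max_drives = np.array([p.max_drive for p in primaries])
    feasible = bool(np.all(bright >= -1e-12) and np.all(dim >= -1e-12)
                    and np.all(bright <= max_drives + 1e-12)
                    and np.all(dim <= max_drives + 1e-12))

    achieved = _achieved_contrasts(primaries, background, delta, lens)
    with np.errstate(divide="ignore", invalid="ignore"):
        modulation = np.where(background.drives > 0,
                              delta / np.where(background.drives > 0,
                                               background.drives, 1.0),
                              np.inf * np.sign(delta))
    diagnostics = {
        "bright_drives": bright, "dim_drives": dim,
        "max_constraint_residual": max(
            (abs(achieved[name] - c) for name, c in constrained), default=0.0),
    }
    sol = SubstitutionSolution(modulation, delta, achieved, feasible, spec,
                               diagnostics)
    if not feasible:
        sol.diagnostics["infeasibility"] = (
            f"drives out of gamut: bright {bright}, dim {dim}")
    return sol


def validate_solution(solution: SubstitutionSolution, primaries, background,
                      bounds: dict, lens: LensFilter | None = None) -> dict:
    """Recompute every opsin contrast from first principles and check bounds.

    ``bounds`` maps opsin name to the maximum tolerated absolute Michelson
    contrast. Returns ``{opsin: {"contrast": c, "bound": b, "pass": bool}}``.
    """
    achieved = _achieved_contrasts(primaries, background, solution.delta_drives,
                                   lens)
    report = {}
    for name, bound in bounds.items():
        c = achieved[name]
        report[name] = {"contrast": c, "bound": float(bound),
                        "pass": bool(abs(c) <= bound)}
    report["all_pass"] = all(v["pass"] for k, v in report.items()
                             if isinstance(v, dict))
    return report


@dataclass
class Waveform:
    """Sampled stimulus: drive traces per primary plus contrast traces per opsin.

    ``contrasts[:, k]`` follows the OPSINS ordering. For step stimuli the
    "contrast" traces are flux drives normalized to the high-step flux
    (0 in darkness); for modulations they are signed Michelson fractions
    relative to the background.
    """

    times: np.ndarray
    drives: np.ndarray              # (n_samples, n_primaries)
    contrasts: np.ndarray           # (n_samples, n_opsins)
    kind: str
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.drives < -1e-12):
            raise ValueError("waveform drives must be nonnegative")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + 1.0 / self.sample_rate

    def contrast(self, opsin: str) -> np.ndarray:
        return self.contrasts[:, OPSINS.index(opsin)]

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = {"time_s": self.times}
        for j in range(self.drives.shape[1]):
            cols[f"drive_{j}"] = self.drives[:, j]
        for k, name in enumerate(OPSINS):
            cols[f"contrast_{name}"] = self.contrasts[:, k]
        pd.DataFrame(cols).to_csv(path, index=False)


def build_square_wave(solution: SubstitutionSolution, primaries, background,
                      frequency: float = 0.25, ramp_ms: float = 40.0,
                      n_cycles: int = 6, sample_rate: float = 200.0) -> Waveform:
    """Square-wave modulation (bright phase first) with linear ramps."""
    if not solution.feasible:
        raise ValueError("cannot build a waveform from an infeasible solution")
    period = 1.0 / frequency
    ramp = ramp_ms / 1000.0
    if ramp > period / 2:
        raise ValueError("ramp longer than half the stimulus period")
    n = int(round(n_cycles * period * sample_rate))
    t = np.arange(n) / sample_rate
    phase = np.mod(t, period)
    # +1 during bright phase, -1 during dim, linear ramps centred on the
    # transitions at phase 0 and period/2
    s = np.where(phase < period / 2, 1.0, -1.0)
    if ramp > 0:
        for edge, direction in ((0.0, 1.0), (period / 2, -1.0)):
            in_ramp = np.abs(phase - edge) < ramp / 2
            s[in_ramp] = direction * (phase[in_ramp] - edge) / (ramp / 2)
            if edge == 0.0:  # wrap: end-of-cycle half of the rising ramp
                in_ramp = phase > period - ramp / 2
                s[in_ramp] = (phase[in_ramp] - period) / (ramp / 2)
    nd = background.nd_scale
    drives = nd * (background.drives[None, :]
                   + s[:, None] * solution.delta_drives[None, :])
    achieved = np.array([solution.achieved[name] for name in OPSINS])
    contrasts = s[:, None] * achieved[None, :]
    return Waveform(t, drives, contrasts, "square", sample_rate,
                    meta={"frequency": frequency, "ramp_ms": ramp_ms,
                          "n_cycles": n_cycles, "nd_level": background.nd_level})


def build_step_pair(primaries, background=None, lens: LensFilter | None = None,
                    step_s: float = 10.0, pre_s: float = 10.0,
                    high_drive: float = 1.0, sample_rate: float = 100.0,
                    nd_level: int = 0):
    """Melanopsin-high / melanopsin-low 10 s steps from darkness.

    The high step drives the mid-wavelength primary alone; the low step a
    short+long-wavelength mixture solved to match L- and S-opsin flux.
    Contrast traces hold the per-opsin flux normalized by the high step's
    flux for that opsin, so cone traces are identical across the pair while
    the melanopsin (and rod) traces differ by the reported ratios.
    """
    if len(primaries) < 3:
        raise ValueError("step pair requires at least 3 primaries")
    M = flux_matrix(primaries, lens)
    peaks = [p.spectrum.grid.wavelengths[np.argmax(p.spectrum.values)]
             for p in primaries]
    mid = int(np.argsort(peaks)[len(peaks) // 2])
    short, long_ = int(np.argmin(peaks)), int(np.argmax(peaks))

    high = np.zeros(len(primaries))
    high[mid] = high_drive
    f_high = M @ high
    # match L and S flux with the short+long pair
    A = M[np.ix_([OPSINS.index("S"), OPSINS.index("L")], [short, long_])]
    ab = np.linalg.solve(A, f_high[[OPSINS.index("S"), OPSINS.index("L")]])
    low = np.zeros(len(primaries))
    low[[short, long_]] = ab
    infeasible = bool(np.any(ab < 0))
    f_low = M @ low

    mel_ratio = f_high[OPSINS.index("mel")] / f_low[OPSINS.index("mel")]
    rod_ratio = f_high[OPSINS.index("rod")] / f_low[OPSINS.index("rod")]

    nd = 10.0 ** (-nd_level)
    n = int(round((pre_s + step_s) * sample_rate))
    t = np.arange(n) / sample_rate - pre_s
    on = (t >= 0)

    def _mk(drive_vec, fluxes, label):
        drives = nd * on[:, None] * drive_vec[None, :]
        contrasts = on[:, None] * (fluxes / f_high)[None, :]
        return Waveform(t, drives, contrasts, "step", sample_rate,
                        meta={"label": label, "step_s": step_s, "pre_s": pre_s,
                              "mel_ratio": float(mel_ratio),
                              "rod_ratio": float(rod_ratio),
                              "nd_level": nd_level,
                              "infeasible": infeasible})

    return _mk(high, f_high, "mel_high"), _mk(low, f_low, "mel_low")


def build_white_noise(primaries, background: Background,
                      contrast_amp: float = 0.65, rate: float = 10.0,
                      duration: float = 600.0, seed: int = 0,
                      lens: LensFilter | None = None,
                      marginal: str = "uniform") -> Waveform:
    """Frame-wise independent rod/L/S contrast noise, solved per frame.

    Each 1/rate frame draws independent rod, L- and S-opsin contrasts
    (uniform over +-amp by default) and solves the exact 3-primary drive
    excursion; melanopsin contrast is left free and reported.
    """
    if len(primaries) != 3:
        raise ValueError("white noise solver requires exactly 3 primaries")
    M = flux_matrix(primaries, lens)
    F0 = M @ background.drives
    rows = [OPSINS.index(n) for n in ("rod", "L", "S")]
    A_inv = np.linalg.inv(M[rows, :])

    n_frames = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    if marginal == "uniform":
        c = rng.uniform(-contrast_amp, contrast_amp, size=(n_frames, 3))
    elif marginal == "gaussian":
        c = np.clip(rng.normal(0.0, contrast_amp / 2, size=(n_frames, 3)),
                    -contrast_amp, contrast_amp)
    else:
        raise ValueError(f"unknown marginal {marginal!r}")

    # delta[f, p]: drive excursion for frame f
    delta = c * F0[rows][None, :] @ A_inv.T
    drives = background.drives[None, :] + delta
    bad = np.where(np.any(drives < -1e-12, axis=1)
                   | np.any(drives > np.array([p.max_drive for p in primaries]),
                            axis=1))[0]
    if bad.size:
        f = int(bad[0])
        raise ValueError(
            f"white-noise frame {f} infeasible: drives {drives[f]} out of "
            f"gamut for background variant {background.variant!r}")

    contrasts = (delta @ M.T) / F0[None, :]   # (n_frames, 4), OPSINS order
    t = np.arange(n_frames) / rate
    nd = background.nd_scale
    return Waveform(t, nd * drives, contrasts, "noise", rate,
                    meta={"contrast_amp": contrast_amp, "seed": seed,
                          "marginal": marginal, "nd_level": background.nd_level,
                          "requested": c})
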
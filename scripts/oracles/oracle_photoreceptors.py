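"""Independent oracle computations for photoreceptor-level expected values.

Standalone: does NOT import chromlgn. Direct evaluation of the A1 template
formula and plain trapezoid integration, used once to freeze expected
values into the test suite.
"""
import math

import numpy as np


def a1_template(wl, lmax):
    x = lmax / wl
    a = 0.8795 + 0.0459 * math.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    beta = 0.26 * np.exp(-(((wl - (189.0 + 0.315 * lmax)) / (-40.5 + 0.195 * lmax)) ** 2))
    return alpha + beta


grid = np.arange(330.0, 701.0, 1.0)

# 1) L-opsin (556 nm) template, peak-normalized on the grid, value at 498 nm
curve_L = a1_template(grid, 556.0)
curve_L = curve_L / curve_L.max()
val_498 = curve_L[grid == 498.0][0]
print(f"L(556) normalized sensitivity at 498 nm = {val_498:.10f}")

# 2) Effective flux: Gaussian spectrum peak 460 nm, FWHM 20 nm, amplitude 1,
#    against mel (480 nm) normalized template, unit transmission
sigma = 20.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
spec = np.exp(-0.5 * ((grid - 460.0) / sigma) ** 2)
mel = a1_template(grid, 480.0)
mel = mel / mel.max()
flux = np.trapezoid(spec * mel, grid)
print(f"flux(Gauss460 FWHM20, mel480, lens=1) = {flux:.8f}")
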
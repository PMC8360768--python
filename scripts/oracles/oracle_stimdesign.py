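"""Independent brute-force oracles for substitution-solver expected values.

Standalone: builds its own flux matrix by direct formula evaluation and
trapezoid integration, then scans the one free primary-modulation degree
of freedom on a fine grid (step ~1e-4 of the drive scale) instead of using
an optimizer. Values frozen into tests/test_stimdesign.py.
"""
import math

import numpy as np


def a1(wl, lmax):
    x = lmax / wl
    a = 0.8795 + 0.0459 * math.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    beta = 0.26 * np.exp(-(((wl - (189.0 + 0.315 * lmax)) / (-40.5 + 0.195 * lmax)) ** 2))
    t = alpha + beta
    return t / t.max()


grid = np.arange(330.0, 701.0, 1.0)
lens = 1.0 / (1.0 + np.exp(-(grid - 330.0) / 15.0))
sigma = 20.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
prims = [np.exp(-0.5 * ((grid - p) / sigma) ** 2) for p in (405.0, 460.0, 620.0)]
opsins = {"S": 365.0, "L": 556.0, "rod": 498.0, "mel": 480.0}
M = np.array([[np.trapezoid(p * a1(grid, lm) * lens, grid) for p in prims]
              for lm in opsins.values()])  # rows S,L,rod,mel
iS, iL, iR, iMel = 0, 1, 2, 3

# background: solve S:L:rod flux ratios 0.15 : 1 : 0.42, drives scaled to max 1
d = np.linalg.solve(M[:3, :], np.array([0.15, 1.0, 0.42]))
d = d / d.max()
F0 = M @ d
print("background drives:", d)

# exact rod-isolating solve: rod 45%, S and L silenced
delta = np.linalg.solve(M[:3, :], np.array([0.0, 0.0, 0.45 * F0[iR]]))
print("rod45 mel contrast:", (M[iMel] @ delta) / F0[iMel])
print("rod45 max cone contrast:",
      max(abs(M[iS] @ delta) / F0[iS], abs(M[iL] @ delta) / F0[iL]))


def brute(target_row, other_row, target_c, step=1e-4, z_range=None):
    """Scan delta460; solve d405, d620 from the two cone constraints."""
    best = (np.inf, None)
    A = M[[iS, iL]][:, [0, 2]]
    lo, hi = z_range if z_range is not None else (-d[1], d[1])
    for z in np.arange(lo, hi + step / 2, step):
        rhs = np.array([
            (target_c * F0[iS] if target_row == iS else 0.0) - M[iS, 1] * z,
            (target_c * F0[iL] if target_row == iL else 0.0) - M[iL, 1] * z,
        ])
        sol = np.linalg.solve(A, rhs)
        delta = np.array([sol[0], z, sol[1]])
        if np.any(np.abs(delta) > d):
            continue
        rc = abs(M[iR] @ delta) / F0[iR]
        mc = abs(M[iMel] @ delta) / F0[iMel]
        val = max(rc, mc)
        if val < best[0]:
            best = (val, delta, rc, mc)
    return best


for name, row in (("L75", iL), ("S75", iS)):
    coarse = brute(row, None, 0.75)
    z0 = coarse[1][1]
    fine = brute(row, None, 0.75, step=1e-8, z_range=(z0 - 2e-4, z0 + 2e-4))
    print(f"{name}: coarse(1e-4) = {coarse[0]:.8f}; "
          f"refined = {fine[0]:.10f} (rod {fine[2]:.10f}, mel {fine[3]:.10f})")

# step pair: high = 460 alone (drive 1); low = a*405 + b*620 matching S and L flux
fh = M[:, 1] * 1.0
A = M[[iS, iL]][:, [0, 2]]
ab = np.linalg.solve(A, fh[[iS, iL]])
fl = M[:, [0, 2]] @ ab
print("step-pair a,b:", ab)
print("mel flux ratio high/low:", fh[iMel] / fl[iMel])
print("rod flux ratio high/low:", fh[iR] / fl[iR])
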
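"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the echo-train oracle is a
direct Bloch-rotation simulation over a dense ensemble of dephased
isochromats, and the NNLS oracle enumerates every active set.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def isochromat_cpmg(
    t2: float,
    t1: float,
    flip_deg: float,
    n_echoes: int,
    echo_spacing: float,
    n_iso: int = 512,
) -> np.ndarray:
    """Echo magnitudes of a CPMG train by brute-force isochromat summation.

    Each isochromat carries a (Mx, My, Mz) vector starting along x (ideal 90°
    excitation about y).  Per half echo-spacing it precesses about z by its
    own crusher-dephasing angle (equally spaced over 2π across the ensemble)
    and relaxes (pure decay, no regrowth); refocusing pulses rotate about x.
    With the ensemble size exceeding the highest populated configuration
    order the ensemble average is exact, not approximate.
    """
    flip = np.deg2rad(flip_deg)
    phis = 2.0 * np.pi * np.arange(n_iso) / n_iso  # dephasing per half interval

    e2 = np.exp(-echo_spacing / 2.0 / t2)
    e1 = np.exp(-echo_spacing / 2.0 / t1)

    mx = np.ones(n_iso)
    my = np.zeros(n_iso)
    mz = np.zeros(n_iso)

    cphi, sphi = np.cos(phis), np.sin(phis)
    ca, sa = np.cos(flip), np.sin(flip)

    def half_interval(mx, my, mz):
        # precess about z by phi, then relax
        mx2 = mx * cphi - my * sphi
        my2 = mx * sphi + my * cphi
        return mx2 * e2, my2 * e2, mz * e1

    echoes = np.empty(n_echoes)
    for n in range(n_echoes):
        mx, my, mz = half_interval(mx, my, mz)
        # rotation about x by flip
        my, mz = my * ca - mz * sa, my * sa + mz * ca
        mx, my, mz = half_interval(mx, my, mz)
        echoes[n] = np.abs(np.mean(mx) + 1j * np.mean(my))
    return echoes


def nnls_by_enumeration(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact non-negative least squares by active-set enumeration.

    Solves the unconstrained least-squares problem on every subset of
    columns, keeps solutions that are feasible (all coefficients >= 0 up to
    round-off), and returns the feasible solution with minimal residual.
    Exponential in the number of columns; intended for <= 8 columns.
    """
    n_cols = B.shape[1]
    best_x = np.zeros(n_cols)
    best_res = float(np.dot(y, y))
    for k in range(1, n_cols + 1):
        for subset in combinations(range(n_cols), k):
            sub = B[:, subset]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(coef < -1e-10):
                continue
            coef = np.maximum(coef, 0.0)
            res = y - sub @ coef
            rss = float(res @ res)
            if rss < best_res - 1e-12 * max(best_res, 1.0):
                best_res = rss
                best_x = np.zeros(n_cols)
                best_x[list(subset)] = coef
    return best_x, best_res
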
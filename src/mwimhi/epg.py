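"""Extended phase graph (EPG) forward model for multi-echo spin-echo trains.

Models the echo amplitudes of a CPMG-style train (ideal 90° excitation
followed by ``n_echoes`` refocusing pulses of a common flip angle) by evolving
the magnetization configuration states F+(k), F-(k), Z(k).  Refocusing pulses
below 180° transfer magnetization into longitudinal configuration states and
back, producing stimulated-echo contributions that make the apparent decay
slower than mono-exponential; modelling them is essential when fitting T2
spectra from GRASE data acquired with imperfect refocusing.

Conventions: excitation is an ideal 90° about y (magnetization starts along
x, F0 = 1); refocusing pulses rotate about x; one unit of crusher-gradient
dephasing is applied per half echo-spacing; relaxation is pure decay (no
regrowth of Z0 toward equilibrium, appropriate for echo trains much shorter
than T1).  At a refocusing flip of exactly 180° the longitudinal states are
never populated and the model reduces to exp(-t/T2) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SequenceParams", "epg_decay_curve", "multi_compartment_curve"]


@dataclass(frozen=True)
class SequenceParams:
    """Multi-echo sequence timing parameters.

    Parameters
    ----------
    n_echoes : int
        Number of refocusing pulses / echoes in the train.
    echo_spacing : float
        Time between consecutive echoes, seconds.
    excitation_flip : float
        Excitation flip angle in degrees; only the ideal 90° is modelled.
    t1_assumed : float
        Longitudinal relaxation time (seconds) assumed when evolving stored
        Z states.  Echo amplitudes are insensitive to it near 180° refocusing.
    """

    n_echoes: int = 48
    echo_spacing: float = 0.008
    excitation_flip: float = 90.0
    t1_assumed: float = 1.0

    def __post_init__(self) -> None:
        if self.n_echoes < 1:
            raise ValueError(f"n_echoes must be >= 1, got {self.n_echoes}")
        if self.echo_spacing <= 0:
            raise ValueError(f"echo_spacing must be > 0, got {self.echo_spacing}")
        if self.t1_assumed <= 0:
            raise ValueError(f"t1_assumed must be > 0, got {self.t1_assumed}")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times n * echo_spacing, n = 1..n_echoes (seconds)."""
        return self.echo_spacing * np.arange(1, self.n_echoes + 1)


def _epg_amplitudes(
    t2: np.ndarray,
    t1: np.ndarray,
    flip_rad: np.ndarray,
    n_echoes: int,
    echo_spacing: float,
) -> np.ndarray:
    """Vectorized EPG echo amplitudes.

    ``t2``, ``t1`` and ``flip_rad`` are broadcast to a common 1-D shape (m,);
    returns an array of shape (n_echoes, m).  N+1 configuration orders are
    retained for an N-echo train, which is sufficient for exact echo
    amplitudes (higher orders cannot return to F0 within the train).
    """
    t2, t1, flip_rad = np.broadcast_arrays(
        np.atleast_1d(np.asarray(t2, dtype=float)),
        np.atleast_1d(np.asarray(t1, dtype=float)),
        np.atleast_1d(np.asarray(flip_rad, dtype=float)),
    )
    m = t2.shape[0]
    n_orders = n_echoes + 1

    e2 = np.exp(-echo_spacing / 2.0 / t2)  # transverse decay per half interval
    e1 = np.exp(-echo_spacing / 2.0 / t1)

    half = flip_rad / 2.0
    c2 = np.cos(half) ** 2
    s2 = np.sin(half) ** 2
    sa = np.sin(flip_rad)
    ca = np.cos(flip_rad)

    fp = np.zeros((n_orders, m), dtype=complex)
    fm = np.zeros((n_orders, m), dtype=complex)
    z = np.zeros((n_orders, m), dtype=complex)
    fp[0] = 1.0  # ideal 90° excitation about y: M along x

    echoes = np.empty((n_echoes, m), dtype=float)

    def relax_shift(fp, fm, z):
        fp *= e2
        fm *= e2
        z *= e1
        fp[1:] = fp[:-1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fp[0] = np.conj(fm[0])

    for n in range(n_echoes):
        relax_shift(fp, fm, z)
        # refocusing pulse about x
        fp_new = c2 * fp + s2 * fm - 1j * sa * z
        fm_new = s2 * fp + c2 * fm + 1j * sa * z
        z_new = -0.5j * sa * fp + 0.5j * sa * fm + ca * z
        fp, fm, z = fp_new, fm_new, z_new
        relax_shift(fp, fm, z)
        echoes[n] = np.abs(fp[0])

    return echoes


def _validate(t2: float, t1: float, refocus_flip: float) -> None:
    if t2 <= 0:
        raise ValueError(f"t2 must be > 0 s, got {t2}")
    if t1 <= 0:
        raise ValueError(f"t1 must be > 0 s, got {t1}")
    if not 0 < refocus_flip <= 180:
        raise ValueError(f"refocus_flip must be in (0, 180] degrees, got {refocus_flip}")


def epg_decay_curve(
    t2: float, t1: float, refocus_flip: float, seq: SequenceParams
) -> np.ndarray:
    """Echo-top amplitudes for a single T2 species under imperfect refocusing.

    Parameters
    ----------
    t2, t1 : float
        Relaxation times in seconds.
    refocus_flip : float
        Refocusing flip angle in degrees, in (0, 180].
    seq : SequenceParams
        Echo train timing.

    Returns
    -------
    numpy.ndarray
        Amplitudes at echo times n * echo_spacing, n = 1..n_echoes, with the
        signal immediately after excitation normalized to 1.  Non-negative.
    """
    _validate(t2, t1, refocus_flip)
    amps = _epg_amplitudes(
        np.array([t2]),
        np.array([t1]),
        np.array([np.deg2rad(refocus_flip)]),
        seq.n_echoes,
        seq.echo_spacing,
    )[:, 0]
    return np.maximum(amps, 0.0)


def epg_basis_curves(
    t2s: np.ndarray, t1: float, refocus_flip: float, seq: SequenceParams
) -> np.ndarray:
    """Decay curves for many T2 values at once; shape (n_echoes, len(t2s))."""
    t2s = np.asarray(t2s, dtype=float)
    if np.any(t2s <= 0):
        raise ValueError("all T2 values must be > 0 s")
    if t1 <= 0 or not 0 < refocus_flip <= 180:
        raise ValueError("invalid t1 or refocus_flip")
    amps = _epg_amplitudes(
        t2s,
        np.full_like(t2s, t1),
        np.full_like(t2s, np.deg2rad(refocus_flip)),
        seq.n_echoes,
        seq.echo_spacing,
    )
    return np.maximum(amps, 0.0)


def multi_compartment_curve(
    compartments: list[tuple[float, float, float]],
    refocus_flip: float,
    seq: SequenceParams,
) -> np.ndarray:
    """Weighted sum of single-pool decay curves.

    Parameters
    ----------
    compartments : list of (fraction, t2, t1)
        Signal fraction (>= 0) and relaxation times (seconds) per water pool.
    refocus_flip : float
        Common refocusing flip angle in degrees.
    seq : SequenceParams
        Echo train timing.
    """
    if len(compartments) == 0:
        raise ValueError("compartment list must not be empty")
    fracs = np.array([c[0] for c in compartments], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("compartment fractions must be >= 0")
    t2s = np.array([c[1] for c in compartments], dtype=float)
    t1s = np.array([c[2] for c in compartments], dtype=float)
    if np.any(t2s <= 0) or np.any(t1s <= 0):
        raise ValueError("compartment t2 and t1 must be > 0 s")
    if not 0 < refocus_flip <= 180:
        raise ValueError(f"refocus_flip must be in (0, 180] degrees, got {refocus_flip}")
    amps = _epg_amplitudes(
        t2s, t1s, np.full_like(t2s, np.deg2rad(refocus_flip)), seq.n_echoes, seq.echo_spacing
    )
    return np.maximum(amps @ fracs, 0.0)
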
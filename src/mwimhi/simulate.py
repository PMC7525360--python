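"""Synthetic multi-echo phantoms and cohort tables with known ground truth.

The phantom generator emulates a 48-echo GRASE acquisition of tissue mixing
three water pools — myelin water (T2 ≈ 20 ms), intra/extracellular water
(T2 ≈ 80 ms) and CSF (T2 ≈ 2 s).  Each region draws a voxelwise true MWF
field from a truncated normal with a specified mean and SD, echoes are
synthesized through the EPG forward model at a spatially varying refocusing
flip angle, and i.i.d. Gaussian noise is added at a specified first-echo
SNR.  The cohort generator draws per-subject ROI MHI values and cognitive
scores linearly coupled to MHI with a noise level solved to hit a target
population correlation, mirroring the statistical structure of an MS /
control imaging-cognition study (including per-test missingness).

All randomness flows through one seeded generator per call, so identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epg import SequenceParams, _epg_amplitudes

__all__ = [
    "Region",
    "PhantomSpec",
    "Phantom",
    "CognitiveTestSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "make_toy_fixture",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """Geometric region with its own true-MWF distribution.

    ``geometry`` is ``("box", (x0, x1, y0, y1, z0, z1))`` with half-open
    index bounds, or ``("ball", (cx, cy, cz, radius))`` in voxel units.
    """

    label: str
    geometry: tuple[str, tuple]
    mwf_mean: float = 0.12
    mwf_sd: float = 0.02

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        kind, params = self.geometry
        out = np.zeros(shape, dtype=bool)
        if kind == "box":
            x0, x1, y0, y1, z0, z1 = params
            out[x0:x1, y0:y1, z0:z1] = True
        elif kind == "ball":
            cx, cy, cz, radius = params
            xx, yy, zz = np.ogrid[: shape[0], : shape[1], : shape[2]]
            out = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2
        else:
            raise ValueError(f"unknown geometry kind '{kind}'")
        return out


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic multi-echo phantom.

    ``flip_field`` may be a scalar (uniform refocusing flip, degrees) or a
    3D array matching ``shape``; ``csf_fraction`` likewise (fraction of CSF
    water per voxel).  ``snr`` is mean first-echo tissue signal over the
    noise SD; ``numpy.inf`` disables noise.  Lesion regions carry their own
    (typically reduced) MWF statistics and are reported in a separate mask.
    """

    shape: tuple[int, int, int] = (16, 16, 4)
    regions: tuple[Region, ...] = ()
    lesion_regions: tuple[Region, ...] = ()
    pool_t2s: tuple[float, float, float] = (0.02, 0.08, 2.0)  # myelin, IE, CSF (s)
    pool_t1s: tuple[float, float, float] = (0.6, 1.0, 4.0)
    csf_fraction: float | np.ndarray = 0.0
    flip_field: float | np.ndarray = 165.0
    snr: float = 300.0
    seed: int = 0
    mwf_bounds: tuple[float, float] = (0.01, 0.5)


@dataclass
class Phantom:
    """Generated phantom: data, masks, and ground truth."""

    volume4d: np.ndarray
    wm_mask: np.ndarray
    roi_masks: dict[str, np.ndarray]
    lesion_mask: np.ndarray
    true_mwf: np.ndarray
    true_flip: np.ndarray
    spec: PhantomSpec
    seq: SequenceParams


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Normal draws truncated to ``bounds`` by resampling (exact for sd=0)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, *bounds)))
    out = rng.normal(mean, sd, size)
    bad = (out <= bounds[0]) | (out >= bounds[1])
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= bounds[0]) | (out >= bounds[1])
    return np.clip(out, bounds[0] + 1e-9, bounds[1] - 1e-9)


def generate_phantom(spec: PhantomSpec, seq: SequenceParams | None = None) -> Phantom:
    """Synthesize a 4D multi-echo volume with masks and ground-truth maps.

    Per tissue voxel the pool fractions are (MWF, 1 − MWF − CSF, CSF); the
    decay curve is the fraction-weighted sum of per-pool EPG curves at the
    voxel's refocusing flip.  Overlapping regions are resolved in favour of
    the later region (logged).  Non-tissue voxels are zero signal.
    """
    seq = seq or SequenceParams()
    if not spec.regions:
        raise ValueError("phantom spec must define at least one region")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    true_mwf = np.full(shape, np.nan)
    tissue = np.zeros(shape, dtype=bool)
    roi_masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(shape, dtype=bool)
    for region in spec.regions + spec.lesion_regions:
        m = region.mask(shape)
        if (m & claimed).any():
            logger.info("region '%s' overlaps an earlier region; it wins", region.label)
        claimed |= m
        tissue |= m
        true_mwf[m] = _truncated_normal(
            rng, region.mwf_mean, region.mwf_sd, int(m.sum()), spec.mwf_bounds
        )
        if region in spec.regions:
            roi_masks[region.label] = m

    lesion_mask = np.zeros(shape, dtype=bool)
    for region in spec.lesion_regions:
        lesion_mask |= region.mask(shape)

    flip = np.broadcast_to(np.asarray(spec.flip_field, dtype=float), shape).copy()
    csf = np.broadcast_to(np.asarray(spec.csf_fraction, dtype=float), shape).copy()
    true_flip = np.where(tissue, flip, np.nan)

    n_vox = int(tissue.sum())
    mwf_v = true_mwf[tissue]
    csf_v = np.clip(csf[tissue], 0.0, 1.0 - mwf_v)
    fracs = np.stack([mwf_v, 1.0 - mwf_v - csf_v, csf_v], axis=1)  # (n_vox, 3)
    flips_v = np.deg2rad(flip[tissue])

    t2s = np.asarray(spec.pool_t2s)
    t1s = np.asarray(spec.pool_t1s)
    curves = np.zeros((n_vox, seq.n_echoes))
    chunk = 4096
    for start in range(0, n_vox, chunk):
        sl = slice(start, min(start + chunk, n_vox))
        m = sl.stop - sl.start
        t2_flat = np.tile(t2s, m)
        t1_flat = np.tile(t1s, m)
        flip_flat = np.repeat(flips_v[sl], 3)
        amps = _epg_amplitudes(t2_flat, t1_flat, flip_flat, seq.n_echoes, seq.echo_spacing)
        amps = amps.T.reshape(m, 3, seq.n_echoes)
        curves[sl] = np.einsum("vp,vpe->ve", fracs[sl], amps)

    volume4d = np.zeros(shape + (seq.n_echoes,))
    volume4d[tissue] = curves

    if np.isfinite(spec.snr):
        if spec.snr <= 0:
            raise ValueError("snr must be > 0")
        sigma = float(volume4d[tissue][:, 0].mean()) / spec.snr
        volume4d = volume4d + rng.normal(0.0, sigma, volume4d.shape)

    # lesions are (damaged) WM tissue; lesion exclusion is the ROI stage's job
    wm_mask = tissue
    return Phantom(volume4d, wm_mask, roi_masks, lesion_mask, true_mwf, true_flip,
                   spec, seq)


@dataclass(frozen=True)
class CognitiveTestSpec:
    """Score model for one cognitive test.

    Patient scores follow ``intercept + slope · MHI_roi + Normal(0, σ_ε)``;
    when ``target_r`` is set, σ_ε is solved from
    σ_ε = |slope| · σ_MHI · sqrt(1/r² − 1) so the population correlation
    between MHI and score equals ``target_r``.  Control scores are drawn
    independent of MHI from Normal(control_mean, control_sd).
    """

    control_mean: float
    control_sd: float
    patient_mean: float
    slope: float
    target_r: float | None = None
    noise_sd: float | None = None
    missingness: float = 0.0


def _default_tests() -> dict[str, CognitiveTestSpec]:
    # group means from a typical MS / control cohort; slopes scaled so that
    # a target correlation of -0.49 yields realistic patient score spread
    return {
        "sdmt": CognitiveTestSpec(62.0, 9.0, 56.0, slope=-92.0, target_r=-0.49, missingness=0.0),
        "srt": CognitiveTestSpec(62.0, 8.0, 55.0, slope=-66.0, target_r=-0.44, missingness=0.10),
        "cowat": CognitiveTestSpec(69.0, 9.0, 60.0, slope=-48.0, target_r=-0.32, missingness=0.11),
        "bvmtr": CognitiveTestSpec(56.0, 10.0, 49.0, slope=-39.0, target_r=-0.26, missingness=0.14),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic MS / control cohort table."""

    n_patients: int = 73
    n_controls: int = 22
    rois: tuple[str, ...] = ("cingulum", "slf", "cc")
    patient_mhi_mean: float = 0.30
    patient_mhi_sd: float = 0.08
    control_mhi_mean: float = 0.22
    control_mhi_sd: float = 0.04
    roi_correlation: float = 0.7
    coupling_roi: str = "slf"
    tests: dict[str, CognitiveTestSpec] = field(default_factory=_default_tests)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.coupling_roi not in self.rois:
            raise ValueError(f"coupling_roi '{self.coupling_roi}' not in rois")
        for name, t in self.tests.items():
            if not 0 <= t.missingness < 1:
                raise ValueError(f"test '{name}': missingness must be in [0, 1)")
            if t.target_r is not None and t.target_r == 0 and t.slope != 0:
                raise ValueError(
                    f"test '{name}': target_r = 0 with nonzero slope is unsatisfiable"
                )


def _draw_mhi(
    rng: np.random.Generator, n: int, mean: float, sd: float, n_rois: int, rho: float
) -> np.ndarray:
    """Correlated per-ROI MHI draws via a shared latent severity factor."""
    u = rng.normal(size=(n, 1))
    e = rng.normal(size=(n, n_rois))
    z = rho * u + np.sqrt(1 - rho**2) * e
    return np.maximum(mean + sd * z, 0.01)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a per-subject cohort table.

    Columns: subject_id, group, age, sex, education, ``mhi_<roi>`` per ROI,
    and one column per cognitive test (NaN where the subject "did not
    complete" the test).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_p, n_c = spec.n_patients, spec.n_controls
    n_rois = len(spec.rois)

    mhi_p = _draw_mhi(rng, n_p, spec.patient_mhi_mean, spec.patient_mhi_sd,
                      n_rois, spec.roi_correlation)
    mhi_c = _draw_mhi(rng, n_c, spec.control_mhi_mean, spec.control_mhi_sd,
                      n_rois, spec.roi_correlation)

    rows: dict[str, list] = {
        "subject_id": [f"ms{i:03d}" for i in range(n_p)]
        + [f"hc{i:03d}" for i in range(n_c)],
        "group": ["MS"] * n_p + ["control"] * n_c,
        "age": list(np.clip(rng.normal(50.2, 10.7, n_p), 26, 65))
        + list(np.clip(rng.normal(46.4, 13.5, n_c), 27, 65)),
        "sex": list(rng.choice(["F", "M"], n_p, p=[0.66, 0.34]))
        + list(rng.choice(["F", "M"], n_c, p=[0.64, 0.36])),
        "education": list(np.clip(rng.normal(14.7, 2.2, n_p), 12, 22))
        + list(np.clip(rng.normal(15.8, 2.2, n_c), 12, 22)),
    }
    for j, roi in enumerate(spec.rois):
        rows[f"mhi_{roi}"] = list(mhi_p[:, j]) + list(mhi_c[:, j])

    k = spec.rois.index(spec.coupling_roi)
    for name, t in spec.tests.items():
        if t.target_r is not None:
            sigma = abs(t.slope) * spec.patient_mhi_sd * np.sqrt(1 / t.target_r**2 - 1)
            if t.slope * t.target_r < 0:
                raise ValueError(
                    f"test '{name}': slope and target_r must share a sign"
                )
        elif t.noise_sd is not None:
            sigma = t.noise_sd
        else:
            raise ValueError(f"test '{name}': set either target_r or noise_sd")
        intercept = t.patient_mean - t.slope * spec.patient_mhi_mean
        scores_p = intercept + t.slope * mhi_p[:, k] + rng.normal(0, sigma, n_p)
        scores_c = rng.normal(t.control_mean, t.control_sd, n_c)
        scores = np.concatenate([scores_p, scores_c])
        if t.missingness > 0:
            scores[rng.random(n_p + n_c) < t.missingness] = np.nan
        rows[name] = list(scores)

    return pd.DataFrame(rows)


def make_toy_fixture(seed: int = 2020) -> tuple[Phantom, pd.DataFrame]:
    """Deterministic miniature end-to-end dataset for tests and examples.

    A 16×16×4 phantom with a WM background slab, three tract-like box ROIs
    ("cingulum", "slf", "cc"), one lesion blob overlapping the "slf" ROI,
    a linear refocusing-flip ramp, and a 20-subject cohort table.
    """
    regions = (
        Region("wm_background", ("box", (0, 16, 0, 16, 0, 4)), 0.12, 0.015),
        Region("cingulum", ("box", (1, 6, 2, 14, 0, 4)), 0.10, 0.02),
        Region("slf", ("box", (6, 11, 2, 14, 0, 4)), 0.14, 0.02),
        Region("cc", ("box", (11, 16, 2, 14, 0, 4)), 0.18, 0.02),
    )
    lesions = (Region("lesion", ("ball", (8.0, 8.0, 1.5, 2.0)), 0.04, 0.01),)
    flip = np.linspace(150.0, 175.0, 16).reshape(16, 1, 1) * np.ones((1, 16, 4))
    spec = PhantomSpec(
        shape=(16, 16, 4),
        regions=regions,
        lesion_regions=lesions,
        flip_field=flip,
        snr=200.0,
        seed=seed,
    )
    phantom = generate_phantom(spec)
    cohort = generate_cohort(
        CohortSpec(n_patients=12, n_controls=8, seed=seed + 1)
    )
    return phantom, cohort
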
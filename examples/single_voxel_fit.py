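"""Fit a single voxel's T2 spectrum and read off the myelin water fraction.

Builds a noiseless two-pool decay curve (15% myelin water at T2 = 20 ms,
85% intra/extracellular water at 80 ms) for a 48-echo train with imperfect
refocusing, then runs the full single-voxel pipeline: flip-angle
estimation, regularized NNLS, and MWF extraction.
"""

import numpy as np

from mwimhi import SequenceParams, T2Grid, fit_decay_curve, multi_compartment_curve

seq = SequenceParams()  # 48 echoes, 8 ms spacing
grid = T2Grid()         # 40 log-spaced T2 points, 15 ms - 2 s

true_mwf, flip = 0.15, 155.0
signal = multi_compartment_curve(
    [(true_mwf, 0.020, 1.0), (1 - true_mwf, 0.080, 1.0)], flip, seq
)
rng = np.random.default_rng(0)
signal = signal + rng.normal(0, signal[0] / 300, signal.shape)  # SNR 300

result = fit_decay_curve(signal, grid, seq)

print(f"true MWF        : {true_mwf:.3f}   (fraction of T2 area below 40 ms)")
print(f"fitted MWF      : {result.mwf:.3f}")
print(f"true flip angle : {flip:.1f} deg")
print(f"estimated flip  : {result.estimated_flip:.1f} deg (B1/stimulated-echo correction)")
print(f"misfit chi^2    : {result.chi_squared:.3e}  at mu = {result.regularizer_weight:.2e}")
peaks = grid.t2_values[result.spectrum > 0.01 * result.spectrum.max()]
print(f"spectrum support: {1e3 * peaks.min():.0f} - {1e3 * peaks.max():.0f} ms "
      "(the two water pools, broadened by regularization)")
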
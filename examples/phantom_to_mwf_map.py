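"""Simulate a small GRASE phantom and recover its voxelwise MWF map.

The phantom mixes myelin, intra/extracellular and CSF water pools with a
spatially uniform true MWF distribution; the fit estimates the refocusing
flip per voxel and reports the map-level recovery error.
"""

import numpy as np

from mwimhi import PhantomSpec, Region, T2Grid, fit_volume, generate_phantom

spec = PhantomSpec(
    shape=(10, 10, 2),
    regions=(Region("wm", ("box", (0, 10, 0, 10, 0, 2)), mwf_mean=0.12, mwf_sd=0.02),),
    flip_field=165.0,
    snr=500.0,
    seed=7,
)
phantom = generate_phantom(spec)
result = fit_volume(phantom.volume4d, phantom.wm_mask, T2Grid(), phantom.seq)

fitted = result.mwf_volume[phantom.wm_mask]
truth = phantom.true_mwf[phantom.wm_mask]
print(f"voxels fit           : {result.n_fit} "
      f"({result.n_skipped} skipped, {result.n_window_violations} window violations)")
print(f"true MWF mean (SD)   : {truth.mean():.4f} ({truth.std(ddof=1):.4f})")
print(f"fitted MWF mean (SD) : {fitted.mean():.4f} ({fitted.std(ddof=1):.4f})")
print(f"mean absolute error  : {np.abs(fitted - truth).mean():.4f}")
print(f"mean estimated flip  : {np.nanmean(result.flip_volume):.1f} deg (true 165.0)")
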
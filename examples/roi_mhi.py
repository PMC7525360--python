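"""NAWM ROI construction and the myelin heterogeneity index (MHI).

Uses the toy phantom's ground-truth MWF map: the white-matter mask is
eroded in-plane (3x3x1 box), each tract ROI is intersected with it, lesion
voxels are subtracted, and MWF mean / SD / MHI are computed per ROI.
MHI = SD/mean; higher values mean more heterogeneous (more damaged) myelin.
"""

from mwimhi import make_toy_fixture, roi_stats_table

phantom, _ = make_toy_fixture()
tracts = {k: v for k, v in phantom.roi_masks.items() if k != "wm_background"}

table = roi_stats_table(
    phantom.true_mwf,
    phantom.wm_mask,
    tracts,
    phantom.lesion_mask,
    subject_id="toy",
    min_voxels=20,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nlesion voxels excluded from 'slf': "
      f"{int((tracts['slf'] & phantom.lesion_mask).sum())}")
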
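"""Delineate the apex--base bundle with tractography + track density.

The delineation recipe: track everywhere in the myocardium (FA stop 0.2,
max turn 30 deg), keep streamlines preferentially oriented along the long
axis, rasterise them into a track-density image, threshold, and measure
the recovered structure.
"""

import numpy as np

from myoarch import dti, geometry, phantoms, tracto
from myoarch.core import ScalarVolume

phantom = phantoms.make_fiber_phantom(seed=0)
dwi = phantoms.simulate_dwi(
    phantom, scheme=phantoms.default_scheme(snr=50.0, seed=0))
tf = dti.fit_tensor(dwi)
metrics = dti.tensor_metrics(tf)
mask = dti.segment_myocardium(
    metrics["fa"], ScalarVolume(3 * metrics["adc"].data, tf.affine),
    ScalarVolume(dwi.dw_mean(), tf.affine))

tg = tracto.track(metrics["v1"], metrics["fa"], mask,
                  tracto.TrackingParams(fa_stop=0.2, max_angle=30.0),
                  affine=tf.affine)
filtered = tracto.filter_by_orientation(tg, axis=[0, 0, 1], angle_threshold=30.0)
print(f"{len(tg)} streamlines tracked, {len(filtered)} kept by the "
      "long-axis orientation filter")

tdi = tracto.track_density(filtered, ScalarVolume(np.zeros(mask.shape),
                                                  tf.affine))
bundle = tracto.delineate_singularity(tdi)

gt = phantom.labels == 2
dice = 2 * (bundle & gt).sum() / (bundle.sum() + gt.sum())
frame = geometry.LVFrame(long_axis=[0, 0, 1], origin=[0, 0, 0],
                         slab_normal=[0, -1, 0])
report = tracto.morphometrics(bundle & mask, mask, frame, metrics["fa"],
                              cavity_labels=phantom.cavity_labels)

print(f"Dice vs ground-truth bundle: {dice:.3f}")
print(f"bundle volume {report.volume_cm3:.3f} cm^3, long-axis extent "
      f"{report.dSLA:.1f} mm")
print(f"bundle FA {report.fa_mean_bundle:.3f} +/- {report.fa_sd_bundle:.3f}, "
      f"whole wedge FA {report.fa_mean_heart:.3f} +/- {report.fa_sd_heart:.3f}")
print("A Dice near 1 means the streamline-density mask coincides with the "
      "true triangular bundle; with the phantom's homogeneous diffusivities "
      "the two FA distributions coincide, so any separation seen in real "
      "tissue reflects genuine microstructural contrast.")
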
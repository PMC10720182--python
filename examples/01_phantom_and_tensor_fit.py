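"""Generate the wedge phantom, simulate a diffusion acquisition, fit tensors.

Builds the synthetic basal-inferoseptal wedge (circumferential myocytes
containing a triangular apex--base bundle), simulates a 6-direction
diffusion acquisition at b = 1000 s/mm^2 with Rician noise, fits the
diffusion tensor per voxel, and reports how well the fitted principal
eigenvector v1 recovers the known myocyte orientations.
"""

import numpy as np

from myoarch import dti, phantoms

phantom = phantoms.make_fiber_phantom(seed=0)
print(f"phantom grid {phantom.shape}, voxel {phantom.spacing[0]:.1f} mm, "
      f"bundle voxels: {(phantom.labels == 2).sum()}")

scheme = phantoms.default_scheme(b=1000.0, snr=50.0, seed=0)
dwi = phantoms.simulate_dwi(phantom, scheme=scheme)
tf = dti.fit_tensor(dwi, mask=phantom.myocardium)
metrics = dti.tensor_metrics(tf)

myo = phantom.myocardium
fa = metrics["fa"].data[myo]
v1 = metrics["v1"][myo]
truth = phantom.fibers[myo]
ang = np.degrees(np.arccos(np.clip(np.abs((v1 * truth).sum(-1)), 0, 1)))

print(f"myocardial FA: {fa.mean():.3f} +/- {fa.std():.3f}  "
      "(fixed ex-vivo myocardium sits near 0.3)")
print(f"v1 angular error vs ground truth: mean {ang.mean():.2f} deg, "
      f"median {np.median(ang):.2f} deg at SNR {scheme.snr:g}")
print("Small angular errors mean the fitted eigenvector tracks the true "
      "myocyte orientation voxel by voxel.")
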
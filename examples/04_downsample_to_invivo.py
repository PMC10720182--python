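"""Downsample the tensor field to in-vivo resolutions in log-Euclidean space.

Averaging diffusion tensors through their matrix logarithms keeps them
positive-definite and emulates scanner partial-volume averaging.  The
question: does the apex--base bundle survive at clinical voxel sizes?
"""

import numpy as np

from myoarch import dti, geometry, phantoms
from myoarch.core import TensorField

phantom = phantoms.make_fiber_phantom(seed=0)
dwi = phantoms.simulate_dwi(
    phantom, scheme=phantoms.default_scheme(snr=50.0, seed=0))
tf = dti.fit_tensor(dwi, mask=phantom.myocardium)

for spacing in [(2.0, 2.0, 5.0), (2.5, 2.5, 8.0)]:
    ds = geometry.downsample_tensors_logE(tf, spacing)
    v1 = dti.tensor_metrics(ds)["v1"]
    ang_to_z = np.degrees(np.arccos(np.clip(np.abs(v1[..., 2]), 0, 1)))
    apexbase = ds.mask & (ang_to_z < 30.0)
    print(f"{spacing[0]}x{spacing[1]}x{spacing[2]} mm^3: "
          f"{int(ds.mask.sum())} tissue voxels, "
          f"{int(apexbase.sum())} still showing apex-base orientation")
print("A nonzero count at both resolutions means the bundle's orientation "
      "signature would remain visible at standard in-vivo voxel sizes, "
      "though reduced to a handful of voxels.")
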
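"""Recover fiber orientation from a microCT-like laminar texture.

Renders the phantom's laminar intensity texture on a 3x finer grid
(emulating the microCT-to-DTI resolution ratio), estimates the structure
tensor with the sigma = 6 integration scale, and takes the
smallest-eigenvalue eigenvector as the myocyte direction.
"""

import numpy as np

from myoarch import phantoms, sti

phantom = phantoms.make_fiber_phantom(seed=0)
fine = phantoms.upsample_phantom(phantom, 3)
volume = phantoms.make_microct_phantom(phantom, stripe_period=6.0,
                                       noise_sd=0.0, upsample=3)
print(f"microCT-like volume: {volume.shape}, voxel {volume.spacing[0]:.2f} mm")

J = sti.structure_tensor(volume)
orient = sti.sti_orientation(J)

tissue = fine.labels > 0
ang = np.degrees(np.arccos(np.clip(
    np.abs((orient["fiber"][tissue] * fine.fibers[tissue]).sum(-1)), 0, 1)))
print(f"orientation error vs ground truth: median {np.median(ang):.2f} deg "
      f"over {tissue.sum()} tissue voxels")

bundle = fine.labels == 2
ang_b = np.degrees(np.arccos(np.clip(
    np.abs((orient["fiber"][bundle] * fine.fibers[bundle]).sum(-1)), 0, 1)))
print(f"inside the apex-base bundle: median {np.median(ang_b):.2f} deg")
print("Sub-degree medians show the laminar texture alone pins down the "
      "myocyte axis, the cross-modality counterpart of the tensor fit.")
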
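"""Monodomain wedge study: rule-based vs measured-style fiber fields.

Runs the three-configuration comparison on the EP ROI wedge for a single
pacing protocol: (1) rule-based transmural helix ramp, (2) the
DTI-measured fiber field containing the bundle, (3) the same field plus a
non-conducting holed interface at the bundle border.  Reports activation
delays and pseudo-ECG amplitudes.  Takes a couple of minutes.
"""

from myoarch import epsim, phantoms

phantom = phantoms.ep_wedge_phantom(seed=0)
print(f"EP wedge: {phantom.shape} nodes at {phantom.spacing[0]:.1f} mm, "
      f"bundle fraction {(phantom.labels == 2).sum() / phantom.myocardium.sum():.1%}")

report = epsim.compare_configurations(phantom, pacing_faces=("left",), seed=0)
entry = report["faces"]["left"]

d21 = entry["delta_lat"]["2-1"]
d31 = entry["delta_lat"]["3-1"]
print(f"mean LAT delay, measured vs rule-based: {d21['mean_ms']:.2f} "
      f"+/- {d21['sd_ms']:.2f} ms")
print(f"mean LAT delay, measured+interface vs rule-based: "
      f"{d31['mean_ms']:.2f} +/- {d31['sd_ms']:.2f} ms")
b = entry["bundle_lat"]
print(f"bundle interior LAT: {b['experimental_mean_ms']:.1f} ms without, "
      f"{b['experimental_interface_mean_ms']:.1f} ms with the interface")
aligned = entry["aligned_pair"]
print(f"pseudo-ECG p2p change from the interface: {aligned} (crossing) "
      f"{entry['amp_change_pct_3v2'][aligned]:.1f}%, F1-F2 (reference) "
      f"{entry['amp_change_pct_3v2']['F1-F2']:.1f}%")
print("Positive delays show the measured-style orientations and the "
      "discontinuity barrier slow the paced wavefront; the pair crossing "
      "the bundle shifts far more than the distant reference pair.")
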
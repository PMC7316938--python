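"""Compute the four deviation metrics for one planned/placed implant pair.

A planned implant sits at the origin pointing along +z; the placed one
is shifted 0.8 mm laterally, 0.6 mm deeper, and tilted 5 degrees.
"""

import numpy as np

from implacc import ImplantPose, deviate

planned = ImplantPose(
    patient_id="1", implant_id="1-13", location="13", role="planned",
    shoulder=np.array([0.0, 0.0, 0.0]), apex=np.array([0.0, 0.0, 13.0]),
    length_mm=13.0,
)
tilt = np.radians(5.0)
axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
shoulder = np.array([0.8, 0.0, 0.6])
placed = ImplantPose(
    patient_id="1", implant_id="1-13", location="13", role="placed",
    shoulder=shoulder, apex=shoulder + 13.0 * axis, length_mm=13.0,
)

r = deviate(planned, placed)
print(f"angular deviation : {r.angular_deg:6.2f} deg   (angle between the two axes)")
print(f"global deviation  : {r.global_mm:6.2f} mm    (3D shoulder-to-shoulder distance)")
print(f"lateral deviation : {r.lateral_mm:6.2f} mm    (|A-C|, in the planned shoulder plane)")
print(f"depth deviation   : {r.depth_mm:6.2f} mm    (|A-D|, along the planned axis; "
      f"signed {r.depth_signed_mm:+.2f} = apical)")
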
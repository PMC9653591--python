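"""Reduced-eye optics: how ametropia moves the retina and the magnification.

Converts a refractive error in diopters to the retina's offset from the
second focal plane, the resulting magnification bias, and the diopter
compensation of a pixel-pitch estimate.
"""

from funduscalib import (
    compensate_pitch,
    delta_d_from_diopter,
    diopter_from_delta_d,
    magnification_bias,
    roi_fundus_diameter,
)
import math

for D in (0.0, -3.27, -0.559, 2.0):
    dd = delta_d_from_diopter(D, 17.0)
    bias = 100 * magnification_bias(dd, 17.0)
    print(f"D = {D:+6.2f} D  ->  retina offset {dd:+.3f} mm, magnification bias {bias:+.2f}%")

print()
print(f"1 mm axial elongation is worth {diopter_from_delta_d(1.0, 17.0):+.2f} D")
print(f"45-degree ROI arc on the emmetropic retina: "
      f"{roi_fundus_diameter(math.radians(45), 17.0, 0.0):.3f} mm")
print(f"pitch 6.0 um compensated for a -3.27 D eye: "
      f"{compensate_pitch(6.0, -3.27, 17.0):.3f} um")
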
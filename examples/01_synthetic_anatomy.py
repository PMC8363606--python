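"""Generate a synthetic bifurcation and an OCT-like pullback.

Builds the reference case — a 3.5->3.0 mm tapered main vessel (MV) with
a 2.5 mm side branch (SB) at 60 degrees and a 60% diameter stenosis in
the distal MV — then samples an OCT pullback and prints the numbers a
reader would check first.
"""

import numpy as np

from stentsim.synthetic import (
    AnatomyParams,
    Stenosis,
    generate_bifurcation,
    generate_oct_pullback,
)

params = AnatomyParams(stenoses=(Stenosis("MV", 32.0, 0.6, 8.0),))
anatomy = generate_bifurcation(params)

print(f"carina at {anatomy.carina_arclength:.1f} mm from the MV inlet")
print(f"MV diameter range: {anatomy.mv.diameter.min():.2f}-{anatomy.mv.diameter.max():.2f} mm")
print(f"  (minimum = 3.1 mm local taper x (1 - 0.6) = {3.1 * 0.4:.2f} mm at the lesion)")

pullback = generate_oct_pullback(anatomy, "MV", frame_spacing=0.5, seed=0)
carina_frame = pullback.frames[pullback.carina_frame_index]
areas = [f.lumen_area() for f in pullback.frames]
print(f"{len(pullback.frames)} OCT frames at 0.5 mm spacing, distal to proximal")
print(f"carina frame index {pullback.carina_frame_index} at {carina_frame.arclength:.2f} mm")
print(f"minimum frame lumen area {min(areas):.2f} mm^2 "
      f"(analytic: {np.pi * (anatomy.mv.diameter.min() / 2) ** 2:.2f} mm^2)")
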
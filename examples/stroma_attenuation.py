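"""Radial attenuation of T-cell motion inside the stromal annulus.

Prints the orientation-tensor eigenvalues across the annulus for a few
anisotropy constants k, and a crude estimate of the time a T cell needs
to cross the 15-um stroma when its radial speed is attenuated as
v = v0 exp(-k s) (tangential motion is untouched).
"""

import math

import numpy as np

from isletsim import StromaGeometry, orientation_tensor, penetration_depth

THICKNESS = 15.0
for k in (0.0, 0.3, 0.6, 0.9):
    geom = StromaGeometry(islet_radius=35.0, thickness=THICKNESS, k=k)
    depths = [0.001, 5.0, 10.0, 14.9]  # just inside the outer/inner boundaries
    ratios = []
    for s in depths:
        x = np.array([geom.outer_radius - s, 0.0])
        psi = orientation_tensor(x, geom)
        lo, hi = np.sort(np.linalg.eigvalsh(psi))
        ratios.append(lo / hi)
    # time to cross at unit inward speed: integral of e^{+ks} ds
    crossing = (math.exp(k * THICKNESS) - 1) / k if k > 0 else THICKNESS
    print(f"k = {k:.1f}: radial/tangential ratio at s ~ 0,5,10,15 um -> "
          + ", ".join(f"{r:.3f}" for r in ratios)
          + f";  relative crossing time ~ {crossing/THICKNESS:6.1f}x")

print("\nAt k = 0 the tensor is the identity everywhere (isotropic tissue)."
      "\nAt k = 0.3 the deepest radial motion is attenuated ~90x, and at"
      "\nk >= 0.6 the stroma is an effective barrier on the simulated horizon:"
      "\nthis is the mechanism behind the monotone immune-response delay.")
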
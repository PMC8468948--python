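"""White/dark reference calibration of raw sensor counts to reflectance.

The standard correction is rho = rho_ref * (R - R_dark) / (R_white - R_dark)
per pixel and band, with rho_ref = 0.99 for a 99%-reflectance calibration
tile.  Here the raw cube counts 500 sit between a dark reference of 100 and
a white reference of 900, so every pixel lands at 0.99 * 400/800 = 0.495.
"""

import numpy as np

from kakispec import HyperCube, ReferenceSet, WavelengthAxis, calibrate_reflectance

axis = WavelengthAxis(np.array([450.0, 500.0, 550.0]))
white = HyperCube(np.full((4, 4, 3), 900.0), axis)
dark = HyperCube(np.full((4, 4, 3), 100.0), axis)
refs = ReferenceSet(white=white, dark=dark, rho_ref=0.99)

raw = HyperCube(np.full((4, 4, 3), 500.0), axis)
reflectance = calibrate_reflectance(raw, refs)

print(f"raw counts 500 between dark 100 and white 900 "
      f"-> reflectance {reflectance.data[0, 0, 0]:.3f}")
print(f"white itself -> "
      f"{calibrate_reflectance(white, refs).data[0, 0, 0]:.2f} "
      f"(the tile's known reflectance)")
print(f"dark itself  -> "
      f"{calibrate_reflectance(dark, refs).data[0, 0, 0]:.2f}")
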
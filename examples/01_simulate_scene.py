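"""Generate one synthetic bruised-persimmon scene and inspect its structure.

Builds the default 128x128x60 reflectance cube for a fruit bruised two days
ago, prints the scene's ground-truth geometry and the spectral orderings the
templates guarantee (bruise darker than intact tissue in the visible range,
brighter at the 670 nm chlorophyll band, water-band recovery with day).
"""

import numpy as np

from kakispec import SceneSpec, generate_cube, make_templates

templates = make_templates()
cube, masks = generate_cube(SceneSpec(seed=42), templates, day=2)

print(f"cube shape (rows, cols, bands): {cube.shape}")
print(f"wavelengths: {cube.axis.values[0]:.0f}-{cube.axis.values[-1]:.0f} nm "
      f"in {len(cube.axis)} bands")
print(f"fruit pixels:  {masks['fruit'].sum()}")
print(f"calyx pixels:  {masks['calyx'].sum()}")
print(f"bruise pixels: {masks['bruise'].sum()} "
      f"({100 * masks['bruise'].sum() / masks['fruit'].sum():.1f}% of fruit)")

lam = templates.axis.values
vis = (lam >= 450) & (lam <= 660)
i670 = int(np.flatnonzero(lam == 670)[0])
i970 = int(np.flatnonzero(lam == 970)[0])
print("\nmean reflectance 450-660 nm (browning darkens the bruise over days):")
print(f"  intact {templates.intact[vis].mean():.3f}  " +
      "  ".join(f"day{d} {templates.damaged[d][vis].mean():.3f}"
                for d in range(4)))
print("reflectance at 670 nm (ordering flips: bruise > intact):")
print(f"  intact {templates.intact[i670]:.3f}  " +
      "  ".join(f"day{d} {templates.damaged[d][i670]:.3f}" for d in range(4)))
print("reflectance at 970 nm water band (wettest at day 0, drying after):")
print(f"  intact {templates.intact[i970]:.3f}  " +
      "  ".join(f"day{d} {templates.damaged[d][i970]:.3f}" for d in range(4)))
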
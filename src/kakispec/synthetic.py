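"""Synthetic persimmon hypercube generator with ground-truth masks.

The generator emulates the laboratory scene: a single fruit (ellipse) on a
dark background, a darker star-shaped calyx patch at the fruit top, radial
illumination falloff (vignetting), additive Gaussian sensor noise, and —
for the damaged states — a circular bruise whose radius grows with the day
after impact.

The spectral templates encode the qualitative structure of the measured mean
spectra of intact and bruised tissue:

* 450-660 nm: intact reflectance exceeds the bruise, and the bruise darkens
  further with each day (browning pigments accumulate);
* 670 nm: the ordering flips — bruised tissue reflects slightly more than
  intact at the chlorophyll absorption band, for every day;
* 970 nm (water absorption valley): the day-0 bruise is wettest and darkest;
  reflectance recovers monotonically with day as the tissue dries, with
  intact tissue brightest of all.

Absolute reflectance levels are invented fixture values — only the orderings
above are treated as normative, and the test-suite asserts them directly on
the template curves.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SceneSpecError
from .fruitseg import write_mask
from .hypercube import (
    FORMAT_PORTABLE,
    REFLECTANCE,
    HyperCube,
    WavelengthAxis,
    default_axis,
    write_cube,
)

STATES = ("intact", "0", "1", "2", "3")
DAYS = (0, 1, 2, 3)

#: per-day bruise radii in pixels at the default 128x128 scale; the damaged
#: area grows with time after impact
DEFAULT_BRUISE_RADII = {0: 8.0, 1: 10.0, 2: 12.0, 3: 14.0}


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and noise of one synthetic scene."""

    shape: tuple = (128, 128)
    fruit_center: tuple = (66.0, 64.0)
    fruit_axes: tuple = (44.0, 40.0)          # (row semi-axis, col semi-axis)
    calyx_center: tuple | None = None          # default: on the fruit top
    calyx_radius: float = 18.0
    calyx_points: int = 5
    bruise_center: tuple | None = None         # default: offset from centre
    bruise_radii: dict = field(default_factory=lambda: dict(DEFAULT_BRUISE_RADII))
    vignette_strength: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def resolved_calyx_center(self) -> tuple:
        if self.calyx_center is not None:
            return self.calyx_center
        return (self.fruit_center[0] - self.fruit_axes[0], self.fruit_center[1])

    def resolved_bruise_center(self) -> tuple:
        if self.bruise_center is not None:
            return self.bruise_center
        return (self.fruit_center[0] + 6.0, self.fruit_center[1] + 9.0)

    def validate(self) -> None:
        radii = [self.bruise_radii[d] for d in DAYS]
        if any(r2 < r1 for r1, r2 in zip(radii, radii[1:])):
            raise SceneSpecError("bruise radius must be nondecreasing in day")
        br, bc = self.resolved_bruise_center()
        fr, fc = self.fruit_center
        ar, ac = self.fruit_axes
        rmax = max(radii)
        # the bruise disc (largest day) must sit fully inside the ellipse
        margin = ((br - fr) / (ar - rmax)) ** 2 + ((bc - fc) / (ac - rmax)) ** 2
        if ar <= rmax or ac <= rmax or margin > 1.0:
            raise SceneSpecError("bruise disc extends outside the fruit ellipse")


@dataclass(frozen=True)
class SpectralTemplates:
    """Reflectance curves for each scene material over the wavelength axis."""

    axis: WavelengthAxis
    intact: np.ndarray
    damaged: dict            # day -> (bands,) curve
    calyx: np.ndarray
    background: np.ndarray
    contrast: float


def _gauss(lam: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((lam - mu) / sigma) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_templates(contrast: float = 1.0,
                   axis: WavelengthAxis | None = None) -> SpectralTemplates:
    """Build smooth template curves; ``contrast`` scales the intact-vs-bruise
    separation, with contrast -> 0 collapsing every bruise onto intact."""
    if not (0 <= contrast <= 1):
        raise ParameterError("contrast must be in [0, 1]")
    axis = axis if axis is not None else default_axis()
    lam = axis.values

    # intact fruit: moderate VIS, chlorophyll dip at 670, bright NIR plateau,
    # water absorption valley at 970
    intact = (0.25 + 0.45 * _sigmoid((lam - 610.0) / 22.0)
              - 0.08 * _gauss(lam, 670.0, 10.0)
              - 0.20 * _gauss(lam, 970.0, 28.0))

    # bruise deviation shapes
    vis = _sigmoid((655.0 - lam) / 6.0)        # ~1 below 640 nm, ~0 past 670
    red_edge = _gauss(lam, 670.0, 8.0)         # chlorophyll-band bump
    water = _gauss(lam, 970.0, 20.0)           # water valley deepening

    damaged = {}
    for d in DAYS:
        a_d = 0.06 + 0.04 * d     # VIS darkening grows with day
        b_d = 0.06 + 0.01 * d     # 670 nm excess, present at every day
        c_d = 0.16 - 0.04 * d     # water-band deficit shrinks with day
        delta = a_d * vis - b_d * red_edge + c_d * water
        damaged[d] = intact - contrast * delta

    calyx = (0.08 + 0.06 * _gauss(lam, 550.0, 40.0)
             + 0.04 * _sigmoid((lam - 720.0) / 30.0))
    background = np.full_like(lam, 0.03)
    return SpectralTemplates(axis=axis, intact=intact, damaged=damaged,
                             calyx=calyx, background=background,
                             contrast=contrast)


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def _star_mask(shape, center, radius, points) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)
    r_theta = radius * (0.65 + 0.35 * np.cos(points * theta))
    return dist <= r_theta


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


def generate_cube(spec: SceneSpec, templates: SpectralTemplates,
                  day: str | int = "intact"):
    """Render one scene.

    ``day`` is "intact" or a day in {0, 1, 2, 3} (int or string).  Returns
    ``(cube, masks)`` where ``masks`` is a dict with ground-truth boolean
    images ``fruit``, ``calyx`` and ``bruise``.  The cube is reflectance
    tagged and fully determined by ``spec.seed``.
    """
    spec.validate()
    state = str(day)
    if state not in STATES:
        raise ParameterError(f"day must be one of {STATES}, got {day!r}")
    shape = spec.shape
    n_bands = len(templates.axis)

    ellipse = _ellipse_mask(shape, spec.fruit_center, spec.fruit_axes)
    calyx = _star_mask(shape, spec.resolved_calyx_center(),
                       spec.calyx_radius, spec.calyx_points)
    fruit = ellipse & ~calyx
    if state == "intact":
        bruise = np.zeros(shape, dtype=bool)
    else:
        bruise = _disc_mask(shape, spec.resolved_bruise_center(),
                            spec.bruise_radii[int(state)]) & fruit

    data = np.empty(shape + (n_bands,))
    data[:, :] = templates.background
    data[ellipse] = templates.intact
    data[calyx] = templates.calyx
    if state != "intact":
        data[bruise] = templates.damaged[int(state)]

    if spec.vignette_strength:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        r2 = (((rr - (shape[0] - 1) / 2) / (shape[0] / 2)) ** 2
              + ((cc - (shape[1] - 1) / 2) / (shape[1] / 2)) ** 2)
        data *= (1.0 - spec.vignette_strength * r2 / 2.0)[:, :, None]

    if spec.noise_sd:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.5)

    cube = HyperCube(data, templates.axis, REFLECTANCE)
    return cube, {"fruit": fruit, "calyx": calyx, "bruise": bruise}


@dataclass(frozen=True)
class SceneDistribution:
    """Random jitter applied to the base scene from cube to cube."""

    base: SceneSpec = SceneSpec()
    center_jitter: float = 3.0
    axis_jitter_frac: float = 0.08
    bruise_center_jitter: float = 4.0

    def draw(self, rng: np.random.Generator, seed: int) -> SceneSpec:
        b = self.base
        fr = b.fruit_center[0] + rng.uniform(-1, 1) * self.center_jitter
        fc = b.fruit_center[1] + rng.uniform(-1, 1) * self.center_jitter
        ar = b.fruit_axes[0] * (1 + rng.uniform(-1, 1) * self.axis_jitter_frac)
        ac = b.fruit_axes[1] * (1 + rng.uniform(-1, 1) * self.axis_jitter_frac)
        br = fr + 6.0 + rng.uniform(-1, 1) * self.bruise_center_jitter
        bc = fc + 9.0 + rng.uniform(-1, 1) * self.bruise_center_jitter
        return replace(b, fruit_center=(fr, fc), fruit_axes=(ar, ac),
                       bruise_center=(br, bc), calyx_center=None, seed=seed)


def iterate_dataset(n_per_class: int,
                    dist: SceneDistribution | None = None,
                    templates: SpectralTemplates | None = None,
                    seed: int = 0):
    """Yield ``(index, state, cube, masks)`` for a balanced synthetic dataset.

    Deterministic per seed; scenes are drawn from ``dist`` and each cube gets
    its own sub-seed, so the sequence is reproducible item by item.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    dist = dist if dist is not None else SceneDistribution()
    templates = templates if templates is not None else make_templates()
    rng = np.random.default_rng(seed)
    idx = 0
    for state in STATES:
        for _ in range(n_per_class):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = dist.draw(rng, sub_seed)
            cube, masks = generate_cube(spec, templates, state)
            yield idx, state, cube, masks
            idx += 1


def generate_dataset(n_per_class: int, out_dir: str,
                     dist: SceneDistribution | None = None,
                     templates: SpectralTemplates | None = None,
                     seed: int = 0) -> str:
    """Write a balanced dataset to ``out_dir`` and return the manifest path.

    Each cube lands as a portable container next to PNG ground-truth masks;
    the manifest CSV (columns: path, state, fruit_mask, calyx_mask,
    bruise_mask, seed) indexes them.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    rows = []
    for idx, state, cube, masks in iterate_dataset(n_per_class, dist,
                                                   templates, seed):
        stem = f"cube_{idx:04d}_{state}"
        cube_path = os.path.join(out_dir, stem + ".npz")
        write_cube(cube, cube_path, FORMAT_PORTABLE)
        mask_paths = {}
        for name in ("fruit", "calyx", "bruise"):
            mpath = os.path.join(out_dir, f"{stem}_{name}.png")
            write_mask(masks[name], mpath, source=cube_path)
            mask_paths[name] = mpath
        rows.append({"path": cube_path, "state": state,
                     "fruit_mask": mask_paths["fruit"],
                     "calyx_mask": mask_paths["calyx"],
                     "bruise_mask": mask_paths["bruise"],
                     "seed": seed})
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "state", "fruit_mask",
                                                "calyx_mask", "bruise_mask",
                                                "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
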
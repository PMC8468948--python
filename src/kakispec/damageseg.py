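"""Bruise detection inside the fruit mask.

A second PCA, fitted once on pooled fruit pixels from a small training set of
bruised fruit (after Savitzky-Golay smoothing and SNV), supplies the score
images in which an invisible bruise shows up as a compact region of contrast.
One configurable PC image is thresholded with Otsu's method; the minority
class within the fruit is the damage candidate (a bruise is a localised
subregion, never most of the fruit).  Candidate regions are then filtered on
area, isoperimetric circularity (4*pi*A / P^2) and nearness to the fruit rim,
which removes the long, narrow artefacts that arise from weaker illumination
at the curved fruit edge.  A fruit is declared damaged iff at least one
region survives; the mean raw reflectance spectrum over the surviving pixels
feeds the damage-aging classifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import disk, erosion

from .errors import ContractError, InsufficientDataError, ParameterError
from .fruitseg import CONNECTIVITY_4, otsu_threshold
from .hypercube import HyperCube
from .pca import PCAModel, pca_fit
from .preprocess import savitzky_golay, snv
from .errors import DegenerateDataError

logger = logging.getLogger(__name__)


@dataclass
class DamagePCAConfig:
    """Configuration of the damage PCA and the score image used for Otsu."""

    n_components: int = 8
    selected_pc: int = 6          # 1-based PC-image index
    sg_window: int = 5
    sg_polyorder: int = 2
    sg_deriv: int = 0
    training_per_day: int = 2

    def __post_init__(self):
        if not (1 <= self.selected_pc <= self.n_components):
            raise ParameterError(
                f"selected_pc must be in 1..{self.n_components}"
            )


@dataclass
class RegionFilter:
    """Thresholds that a candidate damage region must pass.

    ``max_boundary_fraction`` bounds the fraction of region pixels lying in a
    rim of ``rim_width`` pixels inside the fruit boundary; edge artefacts hug
    the rim, genuine bruises do not.
    """

    min_area: int = 1
    min_area_fruit_fraction: float = 0.002   # overrides min_area when set
    min_circularity: float = 0.3
    max_boundary_fraction: float = 0.5
    rim_width: int = 3

    def __post_init__(self):
        if self.min_area < 1:
            raise ParameterError("min_area must be >= 1")
        if not (0 <= self.min_circularity <= 1):
            raise ParameterError("min_circularity must be in [0, 1]")

    def effective_min_area(self, fruit_area: int) -> int:
        if self.min_area_fruit_fraction:
            return max(self.min_area,
                       int(round(self.min_area_fruit_fraction * fruit_area)))
        return self.min_area


@dataclass
class Region:
    area: int
    circularity: float
    centroid: tuple
    boundary_fraction: float


@dataclass
class DamageResult:
    """Per-fruit verdict plus the evidence behind it."""

    verdict: str                      # "intact" | "damaged"
    damage_mask: np.ndarray           # bool, empty iff intact
    regions: list = field(default_factory=list)
    mean_damage_spectrum: np.ndarray | None = None
    degenerate: bool = False          # no spectral contrast in the PC image

    def __post_init__(self):
        has_pixels = bool(self.damage_mask.any())
        if (self.verdict == "damaged") != has_pixels:
            raise ContractError("verdict inconsistent with damage mask")
        if (self.mean_damage_spectrum is not None) != (self.verdict == "damaged"):
            raise ContractError("mean spectrum present iff damaged")

    def to_json_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "degenerate": self.degenerate,
            "regions": [
                {"area": r.area, "circularity": r.circularity,
                 "centroid": list(r.centroid),
                 "boundary_fraction": r.boundary_fraction}
                for r in self.regions
            ],
            "mean_damage_spectrum": (
                None if self.mean_damage_spectrum is None
                else self.mean_damage_spectrum.tolist()
            ),
        }


def region_perimeter(region_mask: np.ndarray) -> float:
    """Boundary-walk perimeter: total length of the outer 0.5-level contour.

    Interior holes are filled first so only the outer boundary counts; the
    walk is the marching-squares contour of the padded binary image, its
    length the sum of the step lengths along it.
    """
    m = np.asarray(region_mask, dtype=bool)
    filled = ndimage.binary_fill_holes(m)
    padded = np.pad(filled.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        steps = np.diff(contour, axis=0)
        total += float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    return total


def circularity(region_mask: np.ndarray) -> float:
    """Isoperimetric circularity 4*pi*A / P^2, capped at 1.0.

    A is the pixel count and P the boundary-walk perimeter of the outer
    boundary.  A single pixel (perimeter ~2.83 < sqrt(4*pi)) caps at 1.0.
    """
    m = np.asarray(region_mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        raise ContractError("circularity of an empty region is undefined")
    p = region_perimeter(m)
    if p <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / (p * p))


def _preprocess_fruit_spectra(X: np.ndarray, cfg: DamagePCAConfig) -> np.ndarray:
    X = savitzky_golay(X, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
    return snv(X)


def fit_damage_pca(training: list, cfg: DamagePCAConfig) -> PCAModel:
    """Fit the damage PCA on pooled fruit pixels of the training cubes.

    ``training`` is a list of ``(HyperCube, fruit_mask)`` pairs — typically
    two bruised fruit per day after damage induction.  Each pixel spectrum is
    Savitzky-Golay smoothed and SNV-normalised before the fit.  The fit is
    deterministic given its inputs; randomness lives only in how the training
    images are sampled upstream.
    """
    if not training:
        raise InsufficientDataError("no training cubes supplied")
    blocks = []
    for cube, mask in training:
        if mask.shape != cube.shape[:2]:
            raise ContractError("fruit mask does not match cube grid")
        blocks.append(cube.spectra(mask))
    X = np.vstack(blocks)
    if X.shape[0] < 10 * cfg.n_components:
        raise InsufficientDataError(
            f"{X.shape[0]} fruit pixels is too few for "
            f"{cfg.n_components} components"
        )
    return pca_fit(_preprocess_fruit_spectra(X, cfg), cfg.n_components)


def _rim_mask(fruit_mask: np.ndarray, width: int) -> np.ndarray:
    if width < 1:
        return np.zeros_like(fruit_mask)
    return fruit_mask & ~erosion(fruit_mask, disk(width)).astype(bool)


def segment_damage(
    cube: HyperCube,
    fruit_mask: np.ndarray,
    model: PCAModel,
    cfg: DamagePCAConfig = DamagePCAConfig(),
    filt: RegionFilter = RegionFilter(),
) -> DamageResult:
    """Detect the bruise (if any) inside the fruit mask.

    Fruit pixels are preprocessed (SG, SNV), projected onto the damage PCA,
    the configured PC score image is Otsu-thresholded over fruit pixels only,
    the minority class is taken as the damage candidate, and candidate
    4-connected regions are filtered by the RegionFilter.
    """
    fruit_mask = np.asarray(fruit_mask, dtype=bool)
    if fruit_mask.shape != cube.shape[:2]:
        raise ContractError("fruit mask does not match cube grid")
    if not fruit_mask.any():
        raise ContractError("fruit mask is empty")
    if cube.n_bands != model.n_bands:
        raise ContractError("model band count does not match cube axis")

    X = cube.spectra(fruit_mask)
    scores = model.transform(_preprocess_fruit_spectra(X, cfg))
    pc_values = scores[:, cfg.selected_pc - 1]

    empty = np.zeros_like(fruit_mask)
    try:
        t = otsu_threshold(pc_values)
    except DegenerateDataError:
        logger.info("segment_damage: degenerate PC image, verdict intact")
        return DamageResult("intact", empty, degenerate=True)

    high = pc_values > t
    # the bruise is a localised region: candidate class = minority class
    candidate = high if high.sum() <= (~high).sum() else ~high
    cand_mask = np.zeros_like(fruit_mask)
    cand_mask[fruit_mask] = candidate

    labels, n = ndimage.label(cand_mask, structure=CONNECTIVITY_4)
    rim = _rim_mask(fruit_mask, filt.rim_width)
    min_area = filt.effective_min_area(int(fruit_mask.sum()))

    kept = []
    damage_mask = np.zeros_like(fruit_mask)
    for lab in range(1, n + 1):
        region = labels == lab
        area = int(region.sum())
        if area < min_area:
            continue
        circ = circularity(region)
        bfrac = float(region[rim].sum()) / area
        if circ < filt.min_circularity or bfrac > filt.max_boundary_fraction:
            continue
        rr, cc = np.nonzero(region)
        kept.append(Region(area=area, circularity=circ,
                           centroid=(float(rr.mean()), float(cc.mean())),
                           boundary_fraction=bfrac))
        damage_mask |= region

    if not kept:
        return DamageResult("intact", empty)
    mean_spec = cube.data[damage_mask].mean(axis=0)
    return DamageResult("damaged", damage_mask, regions=kept,
                        mean_damage_spectrum=mean_spec)


def write_damage_result(result: DamageResult, path_json: str) -> None:
    with open(path_json, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2)
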
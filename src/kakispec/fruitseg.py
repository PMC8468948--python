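"""Fruit-from-background segmentation.

The fruit (and the calyx leaves, which must not count as fruit) is separated
from the dark background without choosing a wavelength by hand: PCA is fitted
on all pixel spectra, the PC1 score image — which carries the bulk of the
scene contrast — is min-max normalised to [0, 1], a greyscale morphological
closing suppresses in-object noise, Otsu's adaptive threshold binarises the
result, and a morphological opening removes small spurious objects near the
boundary.  The largest 4-connected component of the fruit-side class is the
fruit mask.

Otsu's threshold is computed over a 256-bin histogram by maximising the
between-class variance; ties resolve to the lowest qualifying threshold.
Which side of the threshold is "fruit" is decided by mean NIR reflectance
(bands >= 800 nm): fruit tissue is NIR-bright, background and dry calyx are
not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening

from .errors import ContractError, DegenerateDataError, EmptySegmentationError, ParameterError
from .hypercube import HyperCube
from .pca import normalize_pc_image, pca_fit, pca_project

#: 4-connectivity structure used for every connected-component count
CONNECTIVITY_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class StructuringElement:
    """A disk structuring element of integer radius >= 1."""

    radius: int
    shape: str = "disk"

    def __post_init__(self):
        if self.shape != "disk":
            raise ParameterError(f"unsupported structuring element {self.shape!r}")
        if self.radius < 1:
            raise ParameterError("structuring element radius must be >= 1")

    def footprint(self) -> np.ndarray:
        return disk(self.radius)


def otsu_threshold(values, nbins: int = 256) -> float:
    """Between-class-variance-maximising threshold of a 256-bin histogram.

    Returns the upper edge of the best low-class bin, so ``values <= t``
    vs ``values > t`` reproduces the optimal histogram split exactly.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise DegenerateDataError("otsu_threshold needs >= 2 distinct values")
    hist, edges = np.histogram(v, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist / hist.sum()
    omega = np.cumsum(w)                  # P(class0) after bin k
    mu = np.cumsum(w * centers)           # unnormalised class-0 mean
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))           # argmax takes the first (lowest) tie
    return float(edges[k + 1])


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2 or m.dtype != bool:
        raise ContractError("mask must be a 2-D boolean image")
    return m


def morph_close(mask, se: StructuringElement) -> np.ndarray:
    """Binary closing: fills gaps/holes smaller than the element (extensive)."""
    return closing(_as_mask(mask), se.footprint()).astype(bool)


def morph_open(mask, se: StructuringElement) -> np.ndarray:
    """Binary opening: removes objects smaller than the element (anti-extensive)."""
    return opening(_as_mask(mask), se.footprint()).astype(bool)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """The largest 4-connected component, or an error if the mask is empty."""
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_4)
    if n == 0:
        raise EmptySegmentationError("no component survived segmentation")
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def segment_fruit(
    cube: HyperCube,
    close_se: StructuringElement = StructuringElement(3),
    open_se: StructuringElement = StructuringElement(5),
) -> np.ndarray:
    """Segment the fruit: PCA -> PC1 -> normalise -> close -> Otsu -> open.

    The Otsu split labels two classes; the one with higher mean NIR
    reflectance (>= 800 nm) is taken as fruit, and its largest 4-connected
    component after opening is returned.
    """
    if cube.origin != "reflectance":
        raise ContractError("segment_fruit expects a reflectance cube")
    try:
        model = pca_fit(cube.spectra(), 1)
        stack = pca_project(cube, None, model)
        pc1 = normalize_pc_image(stack.image(1))
    except DegenerateDataError as exc:
        raise EmptySegmentationError(f"no scene contrast: {exc}") from exc
    closed = closing(pc1, close_se.footprint())   # greyscale closing
    try:
        t = otsu_threshold(closed)
    except DegenerateDataError as exc:
        raise EmptySegmentationError(f"no scene contrast: {exc}") from exc
    high = closed > t
    # orient the split: fruit is the NIR-bright class
    nir = cube.data[:, :, cube.axis.nir_bands()].mean(axis=2)
    if high.any() and (~high).any():
        fruit_class = high if nir[high].mean() >= nir[~high].mean() else ~high
    else:
        fruit_class = high
    opened = morph_open(fruit_class, open_se)
    if not opened.any():
        raise EmptySegmentationError("opening removed every candidate object")
    return largest_component(opened)


def write_mask(mask: np.ndarray, path: str, *, source: str = "",
               params: dict | None = None) -> None:
    """Write a mask as an 8-bit PNG (0/255) with a JSON sidecar."""
    m = _as_mask(mask)
    iio.imwrite(path, (m.astype(np.uint8) * 255))
    sidecar = {"source": source, "params": params or {},
               "true_pixels": int(m.sum()), "shape": list(m.shape)}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_mask(path: str) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127
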
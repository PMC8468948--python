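"""Spectral preprocessing shared by segmentation and classification.

The operators work on a *spectrum matrix*: a 2-D array with one observation
(pixel or fruit) per row and one band per column.

* Savitzky-Golay smoothing / differentiation — local least-squares polynomial
  filtering along the band axis.  Boundary samples are handled by fitting the
  polynomial to the truncated one-sided window, so the spectrum keeps its
  length.
* SNV (standard normal variate) — per-row standardisation that removes
  multiplicative scatter: each row gets mean 0 and sample (n-1) sd 1.
* Mean centring — per-column centring with means learned on a training matrix
  and reused on test data.
* Cube denoising — a pluggable stage ahead of the PCA steps; the default is
  the identity, with Gaussian spatial smoothing and PCA-truncation
  reconstruction available as alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import savgol_filter

from .errors import ContractError, ParameterError
from .hypercube import HyperCube

logger = logging.getLogger(__name__)


def _check_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ContractError(f"spectrum matrix must be 2-D, got {X.ndim}-D")
    if not np.all(np.isfinite(X)):
        raise ContractError("spectrum matrix contains non-finite values")
    return X


def _check_sg_params(n_bands: int, window: int, polyorder: int, deriv: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    if not (0 <= polyorder < window):
        raise ParameterError(f"polyorder must satisfy 0 <= polyorder < window")
    if not (0 <= deriv <= polyorder):
        raise ParameterError("deriv must satisfy 0 <= deriv <= polyorder")
    if n_bands < window:
        raise ParameterError(
            f"band count {n_bands} smaller than window {window}"
        )


def _one_sided_sg_matrix(window: int, polyorder: int, deriv: int, n: int):
    """Boundary correction rows: least-squares polynomial fit on the
    truncated one-sided window, derivative evaluated at the boundary sample.

    Returns (left, right) matrices of shape (half, n): row i gives the filter
    output at position i (resp. n-1-i from the end) as a linear map of the row.
    """
    import math

    half = window // 2
    left = np.zeros((half, n))
    right = np.zeros((half, n))
    for i in range(half):
        m = i + half + 1  # truncated window size at position i
        order = min(polyorder, m - 1)
        t = np.arange(m, dtype=float)
        V = np.vander(t, order + 1, increasing=True)  # (m, order+1)
        # pinv row for the deriv-th polynomial coefficient, evaluated at t=i
        coef_map = np.linalg.pinv(V)  # (order+1, m)
        # p(t) = sum_k c_k t^k ; p^(deriv)(t0) = sum_{k>=deriv} c_k k!/(k-deriv)! t0^(k-deriv)
        t0 = float(i)
        w = np.zeros(m)
        for k in range(deriv, order + 1):
            scale = math.factorial(k) / math.factorial(k - deriv)
            w += coef_map[k] * scale * t0 ** (k - deriv)
        left[i, :m] = w
        # mirror for the right edge: window is the last m samples, eval at
        # distance i from the end
        t0r = float(m - 1 - i)
        wr = np.zeros(m)
        for k in range(deriv, order + 1):
            scale = math.factorial(k) / math.factorial(k - deriv)
            wr += coef_map[k] * scale * t0r ** (k - deriv)
        right[i, n - m:] = wr
    return left, right


def savitzky_golay(
    X, window: int = 5, polyorder: int = 2, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay filter each row of a spectrum matrix.

    Interior samples use the standard centred window; the ``window // 2``
    samples at each end are re-fit on the truncated one-sided window so that
    any polynomial row of degree <= polyorder is reproduced exactly
    (deriv=0) everywhere.
    """
    X = _check_matrix(X)
    n = X.shape[1]
    _check_sg_params(n, window, polyorder, deriv)
    out = savgol_filter(X, window, polyorder, deriv=deriv, delta=1.0, axis=1,
                        mode="interp")
    # savgol_filter's deriv sign/scale convention matches d/dt with delta=1
    half = window // 2
    if half:
        left, right = _one_sided_sg_matrix(window, polyorder, deriv, n)
        out[:, :half] = X @ left.T
        # right[i] gives the value at position n-1-i; reverse into place
        rvals = X @ right.T
        out[:, n - half:] = rvals[:, ::-1]
    return out


def snv(X) -> np.ndarray:
    """Standard normal variate: centre and scale each row by its own
    mean and sample (n-1) standard deviation.

    Rows with zero spread (flat background pixels) map to all zeros; their
    count is logged rather than raised, so whole-image preprocessing never
    aborts on degenerate pixels.
    """
    X = _check_matrix(X)
    if X.shape[1] < 2:
        raise ParameterError("SNV needs at least 2 bands per row")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    n_deg = int(np.count_nonzero(degenerate))
    if n_deg:
        logger.info("snv: %d degenerate (constant) rows mapped to zeros", n_deg)
    sd = np.where(sd == 0, 1.0, sd)
    out = (X - mean) / sd
    out[degenerate] = 0.0
    return out


@dataclass
class MeanCenter:
    """Per-column centring with means learned from a training matrix."""

    means: np.ndarray

    @classmethod
    def fit(cls, X) -> "MeanCenter":
        X = _check_matrix(X)
        if X.shape[0] < 2:
            raise ParameterError("mean centring needs at least 2 rows to fit")
        return cls(means=X.mean(axis=0))

    def apply(self, X) -> np.ndarray:
        X = _check_matrix(X)
        if X.shape[1] != self.means.size:
            raise ContractError("column count does not match fitted means")
        return X - self.means[None, :]


@dataclass
class SGStep:
    window: int = 5
    polyorder: int = 2
    deriv: int = 0

    def apply(self, X):
        return savitzky_golay(X, self.window, self.polyorder, self.deriv)

    def to_config(self):
        return {"step": "sg", "window": self.window,
                "polyorder": self.polyorder, "deriv": self.deriv}


@dataclass
class SNVStep:
    def apply(self, X):
        return snv(X)

    def to_config(self):
        return {"step": "snv"}


@dataclass
class Recipe:
    """An ordered, serialisable preprocessing pipeline.

    ``mean_center`` steps carry the training means, so applying a fitted
    recipe to held-out spectra reuses the training statistics.
    """

    steps: list = field(default_factory=list)

    def apply(self, X) -> np.ndarray:
        for step in self.steps:
            X = step.apply(X)
        return X

    def to_config(self) -> list:
        out = []
        for step in self.steps:
            if isinstance(step, MeanCenter):
                out.append({"step": "mean_center",
                            "means": step.means.tolist()})
            else:
                out.append(step.to_config())
        return out

    @classmethod
    def from_config(cls, blocks: list) -> "Recipe":
        steps = []
        for blk in blocks:
            kind = blk["step"]
            if kind == "sg":
                steps.append(SGStep(blk["window"], blk["polyorder"],
                                    blk["deriv"]))
            elif kind == "snv":
                steps.append(SNVStep())
            elif kind == "mean_center":
                steps.append(MeanCenter(np.asarray(blk["means"], dtype=float)))
            else:
                raise ParameterError(f"unknown recipe step {kind!r}")
        return cls(steps)


def mean_center_fit(X) -> MeanCenter:
    """Learn per-column means from a training matrix (>= 2 rows)."""
    return MeanCenter.fit(X)


def denoise_cube(cube: HyperCube, method: str = "none", *,
                 sigma: float = 1.0, k: int | None = None) -> HyperCube:
    """Pluggable cube denoising ahead of the PCA stages.

    method="none" is the identity (the default pipeline); "gaussian_spatial"
    smooths each band image with a Gaussian of width ``sigma``;
    "pca_truncate" reconstructs every pixel spectrum from its top-``k``
    principal components, which suppresses band-uncorrelated noise.
    """
    if cube.origin != "reflectance":
        raise ContractError("denoise_cube expects a reflectance-tagged cube")
    if method == "none":
        return cube
    if method == "gaussian_spatial":
        out = np.empty_like(cube.data)
        for b in range(cube.n_bands):
            out[:, :, b] = gaussian_filter(cube.data[:, :, b], sigma=sigma,
                                           mode="nearest")
        return HyperCube(np.clip(out, 0.0, 1.5), cube.axis, cube.origin)
    if method == "pca_truncate":
        if k is None or not (1 <= k < cube.n_bands):
            raise ParameterError(
                f"pca_truncate needs 1 <= k < bands, got k={k}"
            )
        X = cube.spectra()
        mean = X.mean(axis=0)
        Xc = X - mean
        # deterministic SVD-based projection; loadings: (k, bands)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        load = vt[:k]
        recon = (Xc @ load.T) @ load + mean
        recon = np.clip(recon, 0.0, 1.5).reshape(cube.shape)
        return HyperCube(recon, cube.axis, cube.origin)
    raise ParameterError(f"unknown denoise method {method!r}")
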
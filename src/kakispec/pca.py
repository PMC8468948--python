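"""Principal component analysis on pixel spectra.

PCA is fitted on pixels as observations and bands as variables (spectral
PCA), with column centring but no variance scaling.  The solver is a
deterministic SVD; each loading's sign is fixed so that its
largest-magnitude coefficient is positive, making component identities (e.g.
"PC6") stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateDataError, ParameterError
from .hypercube import HyperCube

__all__ = ["PCAModel", "PCImageStack", "pca_fit", "pca_project",
           "normalize_pc_image"]


@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loadings and explained-variance fractions."""

    mean: np.ndarray          # (bands,)
    loadings: np.ndarray      # (components, bands), rows orthonormal
    evr: np.ndarray           # (components,), descending

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_bands(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (n, bands) spectra onto the components -> (n, k) scores."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_bands:
            raise ContractError(
                f"spectra have {X.shape[1]} bands, model expects {self.n_bands}"
            )
        return (X - self.mean) @ self.loadings.T

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            np.savez(fh, mean=self.mean, loadings=self.loadings, evr=self.evr)

    @classmethod
    def load(cls, path: str) -> "PCAModel":
        with np.load(path) as payload:
            return cls(mean=payload["mean"], loadings=payload["loadings"],
                       evr=payload["evr"])


@dataclass
class PCImageStack:
    """Per-pixel PC scores as images, with the valid-pixel mask."""

    scores: np.ndarray   # (rows, cols, components); undefined outside mask
    mask: np.ndarray     # (rows, cols) bool

    def image(self, pc: int) -> np.ndarray:
        """Score image of component ``pc`` (1-based, as in "PC6")."""
        if not (1 <= pc <= self.scores.shape[2]):
            raise ParameterError(f"pc must be in 1..{self.scores.shape[2]}")
        return self.scores[:, :, pc - 1]

    def valid_values(self, pc: int) -> np.ndarray:
        return self.image(pc)[self.mask]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each loading's largest-magnitude coefficient positive."""
    idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(loadings.shape[0]), idx])
    signs[signs == 0] = 1.0
    return loadings * signs[:, None]


def pca_fit(X, n_components: int) -> PCAModel:
    """Fit PCA by SVD of the column-centred matrix.

    evr[i] is the fraction of total variance carried by component i; the
    solver is deterministic, never a randomized approximation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ContractError("pca_fit expects a 2-D spectrum matrix")
    n, p = X.shape
    if not (1 <= n_components <= min(n, p)):
        raise ParameterError(
            f"n_components must be in 1..min(rows, bands)={min(n, p)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise DegenerateDataError("zero total variance: PCA undefined")
    loadings = _fix_signs(vt[:n_components])
    evr = var[:n_components] / total
    return PCAModel(mean=mean, loadings=loadings, evr=evr)


def pca_project(cube: HyperCube, mask: np.ndarray | None,
                model: PCAModel) -> PCImageStack:
    """Project each valid pixel's spectrum onto the model's components.

    Pixels outside ``mask`` are excluded from all downstream statistics;
    their score entries are set to NaN so accidental use is loud.
    """
    if cube.n_bands != model.n_bands:
        raise ContractError(
            f"cube has {cube.n_bands} bands, model expects {model.n_bands}"
        )
    rows, cols, _ = cube.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    elif mask.shape != (rows, cols):
        raise ContractError("mask shape does not match cube spatial grid")
    scores = np.full((rows, cols, model.n_components), np.nan)
    scores[mask] = model.transform(cube.data[mask])
    return PCImageStack(scores=scores, mask=mask.astype(bool))


def normalize_pc_image(img: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalise a score image to [0, 1] over its valid pixels."""
    img = np.asarray(img, dtype=float)
    valid = img[mask] if mask is not None else img.ravel()
    valid = valid[np.isfinite(valid)]
    if valid.size < 2:
        raise DegenerateDataError("need >= 2 valid values to normalise")
    lo, hi = valid.min(), valid.max()
    if hi == lo:
        raise DegenerateDataError("constant image cannot be normalised")
    return (img - lo) / (hi - lo)
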
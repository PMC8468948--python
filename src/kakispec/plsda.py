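"""PLS-DA classification of damage age (days 0-3 after impact).

Each detected-damaged fruit contributes one observation: the mean raw
reflectance spectrum of its damage region.  Spectra are preprocessed with a
Savitzky-Golay derivative (3-point window, 2nd-order polynomial, 1st
derivative) and SNV, then mean-centred, and a PLS2 regression (NIPALS, via
scikit-learn, no variance scaling) is fitted against the dummy-coded day
labels.  Prediction decodes the four indicator outputs by argmax, ties going
to the lowest day.  The number of latent variables is chosen by stratified
10-fold cross-validated misclassification rate, ties going to the fewest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, ParameterError
from .preprocess import Recipe, SGStep, SNVStep

logger = logging.getLogger(__name__)

CLASSES = (0, 1, 2, 3)


def default_recipe(deriv: int = 1) -> Recipe:
    """SG derivative (window 3, polyorder 2) followed by SNV."""
    return Recipe([SGStep(window=3, polyorder=2, deriv=deriv), SNVStep()])


@dataclass
class LabelledSpectra:
    """Mean damage spectra with their day-after-impact labels."""

    X: np.ndarray   # (n, bands)
    y: np.ndarray   # (n,), values in {0, 1, 2, 3}

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ContractError("X rows and y length must match")
        if not np.isin(self.y, CLASSES).all():
            raise ContractError(f"labels must lie in {CLASSES}")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, idx) -> "LabelledSpectra":
        return LabelledSpectra(self.X[idx], self.y[idx])


@dataclass
class PLSDAModel:
    """Preprocessing recipe + linear PLS2 coefficients + argmax decoding."""

    recipe: Recipe
    n_lv: int
    coef: np.ndarray        # (4, bands): row c maps spectrum -> score of class c
    intercept: np.ndarray   # (4,)
    algorithm: str = "nipals"

    def decision_scores(self, X) -> np.ndarray:
        Xp = self.recipe.apply(np.asarray(X, dtype=float))
        if Xp.shape[1] != self.coef.shape[1]:
            raise ContractError(
                f"spectra have {Xp.shape[1]} bands, model expects "
                f"{self.coef.shape[1]}"
            )
        return Xp @ self.coef.T + self.intercept

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            np.savez(fh, coef=self.coef, intercept=self.intercept,
                     n_lv=self.n_lv,
                     recipe=json.dumps(self.recipe.to_config()),
                     algorithm=self.algorithm)

    @classmethod
    def load(cls, path: str) -> "PLSDAModel":
        with np.load(path) as payload:
            return cls(
                recipe=Recipe.from_config(json.loads(str(payload["recipe"]))),
                n_lv=int(payload["n_lv"]),
                coef=payload["coef"],
                intercept=payload["intercept"],
                algorithm=str(payload["algorithm"]),
            )


def _dummy_code(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((y.size, len(CLASSES)))
    Y[np.arange(y.size), y] = 1.0
    return Y


def plsda_fit(data: LabelledSpectra, n_lv: int,
              recipe: Recipe | None = None) -> PLSDAModel:
    """Fit PLS2 on dummy-coded day labels after applying the recipe.

    Mean centring of both blocks is part of the PLS fit (the training means
    are folded into the intercept, so prediction reuses them).
    """
    recipe = recipe if recipe is not None else default_recipe()
    Xp = recipe.apply(data.X)
    n, p = Xp.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ParameterError(f"n_lv must be in 1..min(rows-1, bands)={min(n - 1, p)}")
    present = np.unique(data.y)
    if present.size < len(CLASSES):
        missing = sorted(set(CLASSES) - set(present.tolist()))
        raise ContractError(f"training set lacks classes {missing}")
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(Xp, _dummy_code(data.y))
    # fold the X-centring into the intercept so the model is one affine map:
    # predict(0) = (0 - x_mean) @ coef.T + y_mean
    intercept = pls.predict(np.zeros((1, p)))[0]
    return PLSDAModel(recipe=recipe, n_lv=n_lv,
                      coef=np.asarray(pls.coef_),
                      intercept=np.asarray(intercept))


def plsda_predict(model: PLSDAModel, X) -> np.ndarray:
    """Predicted day labels: argmax over class scores, ties -> lowest day."""
    scores = model.decision_scores(X)
    return np.argmax(scores, axis=1)   # first max wins = lowest day


def select_lv_by_cv(data: LabelledSpectra, max_lv: int, folds: int = 10,
                    seed: int = 0, recipe: Recipe | None = None):
    """Choose the LV count minimising stratified k-fold CV error.

    Returns ``(n_lv, cv_error_curve)`` where the curve's i-th entry is the
    misclassification rate with i+1 latent variables.  Ties resolve to the
    fewest LVs.  If the rarest class has fewer members than ``folds``, the
    fold count is reduced to that class count.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if not (1 <= max_lv <= min(data.n - 1, data.X.shape[1])):
        raise ParameterError("max_lv out of bounds")
    class_min = np.bincount(data.y, minlength=len(CLASSES))
    class_min = class_min[class_min > 0].min()
    if class_min < folds:
        folds = int(class_min)
        if folds < 2:
            raise ParameterError("rarest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(data.X, data.y))
    # every candidate must be fittable on the smallest training fold
    min_fold_train = min(len(tr) for tr, _ in splits)
    if max_lv > min_fold_train - 1:
        logger.info("select_lv_by_cv: capping max_lv at %d (fold size)",
                    min_fold_train - 1)
        max_lv = min_fold_train - 1
    errors = np.zeros(max_lv)
    for lv in range(1, max_lv + 1):
        wrong = 0
        for train_idx, val_idx in splits:
            train = data.subset(train_idx)
            if np.unique(train.y).size < len(CLASSES):
                raise ContractError("a CV fold lost a class entirely")
            model = plsda_fit(train, lv, recipe=recipe)
            pred = plsda_predict(model, data.X[val_idx])
            wrong += int((pred != data.y[val_idx]).sum())
        errors[lv - 1] = wrong / data.n
    best = int(np.argmin(errors)) + 1   # first min = fewest LVs
    return best, errors


@dataclass
class ConfusionReport:
    """A 4x4 count matrix with per-class and total percent correct."""

    counts: np.ndarray                      # (4, 4): rows true, cols predicted
    per_class_pct: np.ndarray = field(init=False)
    total_pct: float = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        row_sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pct = 100.0 * np.diag(self.counts) / np.where(row_sums == 0, 1,
                                                          row_sums)
        self.per_class_pct = pct
        total = self.counts.sum()
        self.total_pct = float(100.0 * np.trace(self.counts) / total) \
            if total else float("nan")

    def to_frame(self):
        import pandas as pd

        labels = [f"{c} d" for c in CLASSES]
        frame = pd.DataFrame(self.counts, index=labels, columns=labels)
        frame["% correct"] = np.round(self.per_class_pct, 1)
        return frame


def confusion(true_labels, predicted_labels) -> ConfusionReport:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ContractError("label vectors differ in length")
    if not (np.isin(t, CLASSES).all() and np.isin(p, CLASSES).all()):
        raise ContractError(f"labels must lie in {CLASSES}")
    counts = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionReport(counts)
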
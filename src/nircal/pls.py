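"""PLS1 regression (NIPALS), cross-validated latent-variable selection,
and prediction.

The model is the classical NIPALS sequence on column-centered X and
centered y: for each latent variable, the weight vector w is the
(normalized) covariance X'y, the score t = Xw, the loadings p = X't/t't
and q = y't/t't, and X is deflated by t p'. The regression vector on
centered data is b = W (P'W)^-1 q. No unit-variance scaling is applied to
X: centering-only is the NIR convention, and scatter/variance structure is
handled by the pretreatments.

Cross-validation uses deterministic venetian-blind folds (sample i goes to
fold i mod folds); the latent-variable count is the argmin of RMSECV, with
ties resolved toward the smaller (more parsimonious) count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from nircal.errors import IncompatibleAxisError
from nircal.io import SpectraSet
from nircal.preprocess import Preprocessor

logger = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """A fitted PLS1 model plus everything needed to reapply it.

    W (weights), P (x-loadings) and q (y-loadings) are stored per latent
    variable; ``b`` is the regression vector on centered data and is
    reproducible from them as b = W (P'W)^-1 q. ``wavelength_indices``
    records the variable subset the model was fit on, relative to
    ``axis_nm`` (the full parent wavelength axis); ``preprocessor`` is the
    frozen pretreatment applied before column subsetting.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k)
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    coefficients: np.ndarray  # (p,)
    n_lvs: int
    wavelength_indices: Optional[np.ndarray] = None
    axis_nm: Optional[np.ndarray] = None
    preprocessor: Optional[Preprocessor] = None

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict from an already-preprocessed, already-subset matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coefficients + self.y_mean

    def to_dict(self) -> dict:
        d = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "n_lvs": int(self.n_lvs),
        }
        if self.wavelength_indices is not None:
            d["wavelength_indices"] = np.asarray(self.wavelength_indices).tolist()
        if self.axis_nm is not None:
            d["axis_nm"] = np.asarray(self.axis_nm).tolist()
        if self.preprocessor is not None:
            d["preprocessor"] = self.preprocessor.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            n_lvs=int(d["n_lvs"]),
            wavelength_indices=(
                np.asarray(d["wavelength_indices"], dtype=int)
                if "wavelength_indices" in d
                else None
            ),
            axis_nm=np.asarray(d["axis_nm"], dtype=float) if "axis_nm" in d else None,
            preprocessor=(
                Preprocessor.from_dict(d["preprocessor"]) if "preprocessor" in d else None
            ),
        )


@dataclass
class CVResult:
    rmsecv_by_lv: np.ndarray  # index j -> RMSECV at j+1 latent variables
    chosen_lvs: int
    fold_assignment: np.ndarray

    @property
    def rmsecv(self) -> float:
        """RMSECV at the chosen latent-variable count."""
        return float(self.rmsecv_by_lv[self.chosen_lvs - 1])

    def to_dict(self) -> dict:
        return {
            "rmsecv_by_lv": np.asarray(self.rmsecv_by_lv).tolist(),
            "chosen_lvs": int(self.chosen_lvs),
            "fold_assignment": np.asarray(self.fold_assignment).tolist(),
        }


def _nipals(Xc: np.ndarray, yc: np.ndarray, max_lvs: int):
    """NIPALS PLS1 on centered data. Returns (W, P, q) with as many
    components as could be extracted (early stop when X'y vanishes)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.empty((p, max_lvs))
    P = np.empty((p, max_lvs))
    q = np.empty(max_lvs)
    norm0 = None
    k = 0
    for _ in range(max_lvs):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if norm0 is None:
            norm0 = nw if nw > 0 else 1.0
        if nw <= 1e-13 * norm0:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-28:
            break
        pl = X.T @ t / tt
        ql = float(y @ t) / tt
        X -= np.outer(t, pl)
        y = y - t * ql
        W[:, k], P[:, k], q[k] = w, pl, ql
        k += 1
    return W[:, :k], P[:, :k], q[:k]


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector using the first k components: b = W_k (P_k'W_k)^-1 q_k."""
    return W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lvs: int,
    *,
    wavelength_indices: Optional[np.ndarray] = None,
    axis_nm: Optional[np.ndarray] = None,
    preprocessor: Optional[Preprocessor] = None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_lvs`` latent variables.

    X is the (already preprocessed, already column-subset) calibration
    matrix; the optional keyword arguments attach provenance used by
    `predict` and model serialization.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y has {y.size} entries for {n} samples")
    if n_lvs < 1 or n_lvs > min(n - 1, p):
        raise ValueError(f"n_lvs must be in [1, {min(n - 1, p)}], got {n_lvs}")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; PLS fit is undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals(X - x_mean, y - y_mean, n_lvs)
    if W.shape[1] < n_lvs:
        logger.warning(
            "NIPALS stopped after %d of %d requested latent variables (X exhausted)",
            W.shape[1],
            n_lvs,
        )
    k = W.shape[1]
    b = _coefficients(W, P, q, k)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=b,
        n_lvs=k,
        wavelength_indices=(
            None if wavelength_indices is None else np.asarray(wavelength_indices, dtype=int)
        ),
        axis_nm=None if axis_nm is None else np.asarray(axis_nm, dtype=float),
        preprocessor=preprocessor,
    )


def predict(model: PLSModel, spectra: SpectraSet) -> np.ndarray:
    """Predict the analyte for each spectrum in ``spectra``.

    Applies the model's frozen preprocessor, subsets to the model's
    wavelength indices, and evaluates the linear model. The spectra must be
    on the model's parent axis (equal length, values within 1e-6 nm).
    """
    if model.axis_nm is not None:
        if spectra.n_wavelengths != model.axis_nm.size:
            raise IncompatibleAxisError(
                f"spectra have {spectra.n_wavelengths} wavelengths, model expects "
                f"{model.axis_nm.size}"
            )
        if np.max(np.abs(spectra.wavelengths_nm - model.axis_nm)) > 1e-6:
            raise IncompatibleAxisError("wavelength axis differs from the model's by > 1e-6 nm")
    if model.preprocessor is not None:
        spectra = model.preprocessor.transform(spectra)
    X = spectra.absorbance
    if model.wavelength_indices is not None:
        X = X[:, model.wavelength_indices]
    if X.shape[1] != model.x_mean.size:
        raise IncompatibleAxisError(
            f"{X.shape[1]} variables after subsetting, model expects {model.x_mean.size}"
        )
    return model.predict_matrix(X)


def _fold_assignment(n: int, folds: int, scheme: str, seed: Optional[int]) -> np.ndarray:
    if scheme == "venetian":
        return np.arange(n) % folds
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return rng.permutation(np.arange(n) % folds)
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lvs: int = 20,
    folds: int = 10,
    scheme: str = "venetian",
    seed: Optional[int] = None,
) -> CVResult:
    """K-fold cross-validation of PLS1 over 1..max_lvs latent variables.

    One NIPALS fit per fold at the largest feasible LV count yields nested
    predictions for every smaller count. ``max_lvs`` is reduced (with a
    logged warning) if a training fold cannot support it. folds = n gives
    leave-one-out.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, {n}], got {folds}")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; cross-validation is undefined")

    assignment = _fold_assignment(n, folds, scheme, seed)
    min_train = min(int(np.sum(assignment != f)) for f in range(folds))
    feasible = min(max_lvs, min_train - 1, p)
    if feasible < max_lvs:
        logger.warning("max_lvs reduced from %d to %d to fit fold sizes", max_lvs, feasible)
    max_lvs = feasible
    if max_lvs < 1:
        raise ValueError("fold sizes leave no room for even one latent variable")

    sq_err = np.zeros(max_lvs)
    for f in range(folds):
        test = assignment == f
        train = ~test
        Xtr, ytr = X[train], y[train]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q = _nipals(Xtr - x_mean, ytr - y_mean, max_lvs)
        Xte_c = X[test] - x_mean
        k_got = W.shape[1]
        last_pred = np.full(int(test.sum()), y_mean)
        for k in range(1, max_lvs + 1):
            if k <= k_got:
                b = _coefficients(W, P, q, k)
                last_pred = Xte_c @ b + y_mean
            sq_err[k - 1] += float(np.sum((last_pred - y[test]) ** 2))

    rmsecv = np.sqrt(sq_err / n)
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest) on ties
    return CVResult(rmsecv_by_lv=rmsecv, chosen_lvs=chosen, fold_assignment=assignment)
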
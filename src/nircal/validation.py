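"""Model validation metrics for NIR calibrations.

Covers the usual calibration/prediction statistics (R2, RMSE, regression
slope) plus two robustness checks from the QSAR validation literature:

* Roy's r2m = r2 * (1 - sqrt(r2 - r2_0)), where r2 is the squared Pearson
  correlation between measured and predicted values and r2_0 the
  through-origin coefficient of determination (k = sum(y*yhat)/sum(yhat^2));
  values above 0.5 indicate measured and predicted values agree beyond mere
  correlation.
* y-randomization: the modelling procedure is rerun on permuted responses
  (same wavelengths; latent-variable count re-chosen by cross-validation,
  as for the real response) and the mean calibration R2 of those null fits
  (R2rand) is folded into cR2P = sqrt(R2C) * sqrt(R2C - R2rand); values
  above 0.5 indicate the calibration is not a chance correlation.

R2 here is the squared Pearson correlation (the convention in the NIR
calibration literature), not the coefficient of determination; use
``r_squared(..., kind="determination")`` for the latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from nircal.errors import DegenerateSpectrumError
from nircal.pls import PLSModel, CVResult, cross_validate, fit_pls, predict
from nircal.io import SpectraSet

logger = logging.getLogger(__name__)

R2M_THRESHOLD = 0.5
CR2P_THRESHOLD = 0.5


def _check_pair(measured, predicted):
    m = np.asarray(measured, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if m.size != p.size:
        raise ValueError(f"length mismatch: {m.size} vs {p.size}")
    if m.size == 0:
        raise ValueError("empty input")
    return m, p


def rmse(measured, predicted) -> float:
    """Root mean square error, denominator n."""
    m, p = _check_pair(measured, predicted)
    return float(np.sqrt(np.mean((m - p) ** 2)))


def r_squared(measured, predicted, kind: str = "pearson") -> float:
    """Squared Pearson correlation (default) or coefficient of determination."""
    m, p = _check_pair(measured, predicted)
    if kind == "pearson":
        if np.ptp(m) == 0 or np.ptp(p) == 0:
            raise DegenerateSpectrumError("constant vector: correlation undefined")
        r = np.corrcoef(m, p)[0, 1]
        return float(r * r)
    if kind == "determination":
        ss_tot = float(np.sum((m - m.mean()) ** 2))
        if ss_tot == 0:
            raise DegenerateSpectrumError("constant measured vector")
        return float(1.0 - np.sum((m - p) ** 2) / ss_tot)
    raise ValueError(f"unknown kind {kind!r}")


def slope(measured, predicted, direction: str = "predicted_on_measured") -> float:
    """OLS slope (intercept included) of predicted regressed on measured
    (default) or the reverse."""
    m, p = _check_pair(measured, predicted)
    if direction == "measured_on_predicted":
        m, p = p, m
    mc = m - m.mean()
    denom = float(mc @ mc)
    if denom == 0:
        raise DegenerateSpectrumError("constant regressor: slope undefined")
    return float(mc @ (p - p.mean()) / denom)


def r2_through_origin(measured, predicted) -> float:
    """r2_0: determination of the through-origin fit y ~ k*yhat,
    k = sum(y*yhat)/sum(yhat^2) (Roy convention)."""
    m, p = _check_pair(measured, predicted)
    denom = float(p @ p)
    if denom == 0:
        raise DegenerateSpectrumError("all-zero predictions: r2_0 undefined")
    k = float(m @ p) / denom
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateSpectrumError("constant measured vector")
    return float(1.0 - np.sum((m - k * p) ** 2) / ss_tot)


def r2m(measured, predicted) -> float:
    """Roy's r2m = r2 * (1 - sqrt(r2 - r2_0)).

    When numerical noise puts r2 below r2_0 the absolute difference is
    used under a logged warning.
    """
    r2 = r_squared(measured, predicted)
    r20 = r2_through_origin(measured, predicted)
    gap = r2 - r20
    if gap < 0:
        logger.warning("r2 (%.6f) < r2_0 (%.6f); using |r2 - r2_0| in r2m", r2, r20)
        gap = abs(gap)
    return float(r2 * (1.0 - np.sqrt(gap)))


def cr2p(r2_c: float, r2_rand: float) -> float:
    """Chance-correlation statistic cR2P = sqrt(R2C) * sqrt(R2C - R2rand)."""
    if r2_rand > r2_c:
        raise ValueError(
            f"R2rand ({r2_rand}) exceeds R2C ({r2_c}); cR2P would be complex"
        )
    return float(np.sqrt(r2_c) * np.sqrt(r2_c - r2_rand))


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    n_lvs: int,
    selected_indices: Optional[np.ndarray] = None,
    n_perm: int = 25,
    seed: int = 0,
    lv_selection: str = "cv",
    cv_folds: int = 10,
) -> tuple[float, np.ndarray]:
    """Mean calibration R2 over refits on permuted responses.

    Each permutation shuffles y, rebuilds the model on the same wavelength
    subset, and records the calibration R2. With ``lv_selection='cv'``
    (default) the null refits rerun the full modelling procedure: the
    latent-variable count is re-chosen by cross-validation in 1..n_lvs,
    exactly as it was for the real response — on scrambled data CV
    collapses to very few components and the null R2 stays near zero.
    ``lv_selection='fixed'`` forces every null refit to use n_lvs
    components; note that for p >> n this measures the interpolation
    capacity of n_lvs forced components rather than chance correlation,
    and is far larger. Returns (mean, per-permutation array).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if lv_selection not in ("cv", "fixed"):
        raise ValueError(f"unknown lv_selection {lv_selection!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if selected_indices is not None:
        X = X[:, np.asarray(selected_indices, dtype=int)]
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_perm)
    for j in range(n_perm):
        y_perm = rng.permutation(y)
        k = n_lvs
        if lv_selection == "cv":
            cv = cross_validate(
                X, y_perm, max_lvs=n_lvs, folds=min(cv_folds, X.shape[0])
            )
            k = cv.chosen_lvs
        model = fit_pls(X, y_perm, k)
        r2s[j] = r_squared(y_perm, model.predict_matrix(X))
    return float(r2s.mean()), r2s


@dataclass
class EvaluationReport:
    """One comparison-table row: calibration, y-randomization and
    prediction statistics for a fitted model."""

    analyte: str
    method: str
    r2_c: float
    rmsec: float
    rmsecv: float
    slope_c: float
    r2_rand: float
    cr2_p: float
    r2_p: float
    rmsep: float
    slope_p: float
    r2_m: float
    n_cal: int
    n_pred: int
    n_lvs: int
    n_variables: int
    gates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "method": self.method,
            "r2_c": self.r2_c,
            "rmsec": self.rmsec,
            "rmsecv": self.rmsecv,
            "slope_c": self.slope_c,
            "r2_rand": self.r2_rand,
            "cr2_p": self.cr2_p,
            "r2_p": self.r2_p,
            "rmsep": self.rmsep,
            "slope_p": self.slope_p,
            "r2_m": self.r2_m,
            "n_cal": self.n_cal,
            "n_pred": self.n_pred,
            "n_lvs": self.n_lvs,
            "n_variables": self.n_variables,
            "gates": dict(self.gates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)

    def table_row(self) -> dict:
        """Row at comparison-table precision (R2-likes at 3 dp, errors and
        slopes at 2 dp); full precision stays in the report itself."""
        return {
            "analyte": self.analyte,
            "method": self.method,
            "LVs": self.n_lvs,
            "variables": self.n_variables,
            "R2C": round(self.r2_c, 3),
            "RMSEC": round(self.rmsec, 2),
            "RMSECV": round(self.rmsecv, 2),
            "slope_cal": round(self.slope_c, 2),
            "R2rand": round(self.r2_rand, 3),
            "cR2P": round(self.cr2_p, 2),
            "R2P": round(self.r2_p, 3),
            "RMSEP": round(self.rmsep, 2),
            "slope_pred": round(self.slope_p, 2),
            "r2m": round(self.r2_m, 3),
        }


def evaluate_model(
    model: PLSModel,
    cal_spectra: SpectraSet,
    y_cal: np.ndarray,
    pred_spectra: SpectraSet,
    y_pred_ref: np.ndarray,
    cv: CVResult,
    analyte: str = "",
    method: str = "",
    n_perm: int = 25,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the full metric row for a fitted model.

    Calibration and prediction sets must be disjoint; the calibration
    design matrix for y-randomization is rebuilt through the model's own
    frozen preprocessor and wavelength subset.
    """
    overlap = set(cal_spectra.sample_ids) & set(pred_spectra.sample_ids)
    if overlap:
        raise ValueError(f"calibration and prediction sets overlap: {sorted(overlap)[:3]}")

    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred_ref = np.asarray(y_pred_ref, dtype=float).ravel()

    yhat_cal = predict(model, cal_spectra)
    yhat_pred = predict(model, pred_spectra)

    # rebuild the preprocessed, subset calibration matrix for null refits
    Xc = cal_spectra
    if model.preprocessor is not None:
        Xc = model.preprocessor.transform(Xc)
    Xmat = Xc.absorbance
    if model.wavelength_indices is not None:
        Xmat = Xmat[:, model.wavelength_indices]

    r2_c = r_squared(y_cal, yhat_cal)
    r2_rand, _ = y_randomization(Xmat, y_cal, model.n_lvs, n_perm=n_perm, seed=seed)
    # guard: an unlucky null draw could nominally exceed r2_c
    cr2 = cr2p(r2_c, min(r2_rand, r2_c))
    r2_m_val = r2m(y_pred_ref, yhat_pred)

    report = EvaluationReport(
        analyte=analyte,
        method=method,
        r2_c=r2_c,
        rmsec=rmse(y_cal, yhat_cal),
        rmsecv=cv.rmsecv,
        slope_c=slope(y_cal, yhat_cal),
        r2_rand=r2_rand,
        cr2_p=cr2,
        r2_p=r_squared(y_pred_ref, yhat_pred),
        rmsep=rmse(y_pred_ref, yhat_pred),
        slope_p=slope(y_pred_ref, yhat_pred),
        r2_m=r2_m_val,
        n_cal=cal_spectra.n_samples,
        n_pred=pred_spectra.n_samples,
        n_lvs=model.n_lvs,
        n_variables=int(model.x_mean.size),
        gates={
            "r2m_pass": bool(r2_m_val >= R2M_THRESHOLD),
            "cr2p_pass": bool(cr2 >= CR2P_THRESHOLD),
        },
    )
    return report
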
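"""Outlier screening and calibration/prediction partitioning.

Outliers: Mahalanobis distance of each spectrum from the population mean,
computed in a PCA score subspace (the raw wavelength covariance is singular
when variables far outnumber samples), with either a Chauvenet-style
rejection rule or a fixed chi-square 95% quantile.

Partitioning: the Kennard-Stone max-min algorithm, which picks a
calibration set spread uniformly over spectral space and leaves the
interior samples for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2

from nircal.io import SpectraSet


@dataclass
class OutlierReport:
    sample_ids: list[str]
    distances: np.ndarray
    threshold: float
    flagged: list[str]
    subspace_dims: int
    rule: str

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "distances": np.asarray(self.distances).tolist(),
            "threshold": float(self.threshold),
            "flagged": self.flagged,
            "subspace_dims": int(self.subspace_dims),
            "rule": self.rule,
        }


@dataclass
class SplitResult:
    calibration_ids: list[str]
    prediction_ids: list[str]
    ratio_requested: float

    def to_dict(self) -> dict:
        return {
            "calibration_ids": self.calibration_ids,
            "prediction_ids": self.prediction_ids,
            "ratio_requested": float(self.ratio_requested),
        }


def mahalanobis_outliers(
    spectra: SpectraSet,
    variance_kept: float = 0.99,
    rule: str = "chauvenet",
) -> OutlierReport:
    """Flag abnormal spectra by Mahalanobis distance in PCA score space.

    The subspace keeps the smallest number of principal components whose
    cumulative explained variance reaches ``variance_kept``; score
    covariance is diagonal there, so the squared distance is a sum of
    standardized squared scores and is chi-square(k) distributed under
    multivariate normality.

    rule='chauvenet' flags sample i when n * P(D > d_i) < 1/2 (the expected
    number of equally extreme samples is below one half); rule='quantile95'
    flags d_i^2 above the chi-square 95% quantile.
    """
    n = spectra.n_samples
    if n < 5:
        raise ValueError(f"outlier screening needs at least 5 samples, got {n}")
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    if rule not in ("chauvenet", "quantile95"):
        raise ValueError(f"unknown rule {rule!r}")

    X = spectra.absorbance - spectra.absorbance.mean(axis=0)
    # thin SVD: at most n-1 non-trivial components
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (n - 1)
    positive = var > (var[0] * 1e-12 if var[0] > 0 else 0)
    var = var[positive]
    ratio = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(ratio, variance_kept - 1e-12) + 1)
    k = min(k, var.size)

    scores = U[:, :k] * s[:k]
    d2 = np.sum(scores**2 / var[:k], axis=1)
    d = np.sqrt(d2)

    if rule == "chauvenet":
        # flag when expected count of equally extreme samples < 1/2
        tail = chi2.sf(d2, df=k)
        flagged_mask = n * tail < 0.5
        threshold = float(np.sqrt(chi2.isf(0.5 / n, df=k)))
    else:
        threshold = float(np.sqrt(chi2.ppf(0.95, df=k)))
        flagged_mask = d > threshold

    flagged = [sid for sid, f in zip(spectra.sample_ids, flagged_mask) if f]
    return OutlierReport(
        sample_ids=list(spectra.sample_ids),
        distances=d,
        threshold=threshold,
        flagged=flagged,
        subspace_dims=k,
        rule=rule,
    )


def kennard_stone(
    spectra: SpectraSet,
    calibration_fraction: float = 2.0 / 3.0,
    calibration_size: int | None = None,
) -> SplitResult:
    """Kennard-Stone max-min split on Euclidean distances between spectra.

    Seeds with the most distant pair, then repeatedly adds the sample whose
    minimum distance to the selected set is largest, until
    round(fraction * n) samples (or ``calibration_size``, if given) are
    selected. Ties break to the lower input row index; the procedure is
    fully deterministic.
    """
    n = spectra.n_samples
    if n < 3:
        raise ValueError(f"Kennard-Stone needs at least 3 samples, got {n}")
    if calibration_size is None:
        if not 0 < calibration_fraction < 1:
            raise ValueError("calibration_fraction must be in (0, 1)")
        n_cal = int(np.floor(calibration_fraction * n + 0.5))
    else:
        n_cal = int(calibration_size)
    if not 2 <= n_cal <= n:
        raise ValueError(f"calibration size {n_cal} not in [2, {n}]")

    D = squareform(pdist(spectra.absorbance, metric="euclidean"))

    # seed: maximum-distance pair, lexicographically first on ties
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))  # argmax returns first occurrence = lowest (i, j)
    selected = [int(iu[0][best]), int(iu[1][best])]
    if selected[0] > selected[1]:
        selected = selected[::-1]

    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(D[selected[0]], D[selected[1]])

    while len(selected) < n_cal:
        min_dist_masked = np.where(in_set, -np.inf, min_dist)
        nxt = int(np.argmax(min_dist_masked))  # first occurrence -> lower index on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])

    cal_ids = [spectra.sample_ids[i] for i in selected]
    pred_ids = [s for i, s in enumerate(spectra.sample_ids) if not in_set[i]]
    return SplitResult(cal_ids, pred_ids, ratio_requested=n_cal / n)
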
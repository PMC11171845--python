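"""Spectral pretreatments: SNV, MSC, Savitzky-Golay smoothing and first
derivative, plus raw passthrough.

All transforms are pure and row-local except MSC, whose reference spectrum
is estimated once on the calibration set and frozen; applying a frozen
`Preprocessor` to prediction spectra therefore never leaks prediction-set
statistics into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from nircal.errors import DegenerateSpectrumError
from nircal.io import SpectraSet

METHODS = ("raw", "snv", "msc", "smoothing", "d1_sg")


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum standardized to mean 0 and
    sample (n-1 denominator) standard deviation 1."""
    X = spectra.absorbance
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum cannot be SNV-normalized: sample {spectra.sample_ids[bad[0]]}"
        )
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra.with_absorbance(out)


def msc(
    spectra: SpectraSet, reference: Optional[np.ndarray] = None
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference spectrum (OLS with
    intercept), x = a + b*ref, and replaced by (x - a)/b. The reference
    defaults to the column mean of the given spectra; pass the frozen
    calibration reference when transforming prediction spectra.
    Returns the corrected spectra and the reference actually used.
    """
    X = spectra.absorbance
    if X.shape[1] < 2:
        raise DegenerateSpectrumError("MSC needs at least 2 wavelengths")
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("MSC reference length does not match wavelength axis")
    ref_centered = ref - ref.mean()
    denom = np.dot(ref_centered, ref_centered)
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference spectrum has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_centered / denom
    small = np.flatnonzero(np.abs(b) < 1e-12)
    if small.size:
        raise DegenerateSpectrumError(
            f"degenerate MSC fit (|slope| < 1e-12) for sample {spectra.sample_ids[small[0]]}"
        )
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    return spectra.with_absorbance(out), ref


def _check_sg(window: int, polyorder: int, n_wavelengths: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"SG window ({window}) must exceed polyorder ({polyorder})")
    if window > n_wavelengths:
        raise ValueError(f"SG window ({window}) exceeds spectrum length ({n_wavelengths})")


def sg_smooth(spectra: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay smoothing; boundary windows use a polynomial fit so
    output length equals input length."""
    _check_sg(window, polyorder, spectra.n_wavelengths)
    out = savgol_filter(spectra.absorbance, window, polyorder, axis=1, mode="interp")
    return spectra.with_absorbance(out)


def d1_sg(spectra: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay first derivative with respect to wavelength (per-nm).

    The grid is uniform in wavenumber, hence slightly non-uniform in nm;
    the per-index SG derivative is divided by the local nm spacing.
    """
    _check_sg(window, max(polyorder, 1), spectra.n_wavelengths)
    if polyorder < 1:
        raise ValueError("first derivative needs polyorder >= 1")
    d_index = savgol_filter(
        spectra.absorbance, window, polyorder, deriv=1, delta=1.0, axis=1, mode="interp"
    )
    local_step = np.gradient(spectra.wavelengths_nm)
    return spectra.with_absorbance(d_index / local_step[None, :])


@dataclass
class PreprocessorSpec:
    """Declarative pretreatment choice, serializable inside model files."""

    method: str = "raw"
    sg_window: int = 11
    sg_polyorder: int = 2

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method in ("smoothing", "d1_sg"):
            _check_sg(self.sg_window, self.sg_polyorder, self.sg_window + 1)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessorSpec":
        return cls(**d)


@dataclass
class Preprocessor:
    """A pretreatment fitted on calibration spectra and frozen.

    For MSC, `fit` stores the calibration column-mean as the reference;
    every other method is stateless. `transform` applied twice to the same
    spectra gives identical output.
    """

    spec: PreprocessorSpec = field(default_factory=PreprocessorSpec)
    msc_reference_: Optional[np.ndarray] = None

    def fit(self, spectra: SpectraSet) -> "Preprocessor":
        if self.spec.method == "msc":
            self.msc_reference_ = spectra.absorbance.mean(axis=0)
        return self

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        m = self.spec.method
        if m == "raw":
            return spectra.with_absorbance(spectra.absorbance.copy())
        if m == "snv":
            return snv(spectra)
        if m == "msc":
            if self.msc_reference_ is None:
                raise RuntimeError("MSC preprocessor must be fitted before transform")
            corrected, _ = msc(spectra, reference=self.msc_reference_)
            return corrected
        if m == "smoothing":
            return sg_smooth(spectra, self.spec.sg_window, self.spec.sg_polyorder)
        if m == "d1_sg":
            return d1_sg(spectra, self.spec.sg_window, self.spec.sg_polyorder)
        raise ValueError(f"unknown method {m!r}")

    def fit_transform(self, spectra: SpectraSet) -> SpectraSet:
        return self.fit(spectra).transform(spectra)

    def to_dict(self) -> dict:
        d = {"spec": self.spec.to_dict()}
        if self.msc_reference_ is not None:
            d["msc_reference"] = self.msc_reference_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        obj = cls(spec=PreprocessorSpec.from_dict(d["spec"]))
        if "msc_reference" in d:
            obj.msc_reference_ = np.asarray(d["msc_reference"], dtype=float)
        return obj
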
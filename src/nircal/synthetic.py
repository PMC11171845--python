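"""Synthetic NIR spectra and antioxidant reference values.

The generator emulates the statistical structure of diffuse-reflectance
NIR measurements of powdered herbal material: a handful of latent chemical
components, each contributing overlapping Gaussian absorption bands at the
hydrogen-bond overtone/combination positions that dominate this spectral
region (O-H near 1440 and 1940 nm; C-H near 1210, 1730, 2280 and 2330 nm),
corrupted per spectrum by a multiplicative scatter gain, an additive
baseline offset and white detector noise. Reference antioxidant values
(ABTS %, FRAP umol/L, DPPH %) are affine in the latent concentrations,
rescaled into realistic assay ranges, with assay noise added.

The assay arithmetic used by wet-lab reference methods is implemented
separately (`clearance_capacity`, `frap_concentration`) so that the path
from raw absorbances to reference values is exercised by the same code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from nircal.errors import InvalidMeasurementError
from nircal.io import SpectraSet, ReferenceTable

# Target ranges the rescaled reference values fall in: ABTS clearance %,
# FRAP FeSO4-equivalent umol/L, DPPH clearance %.
DEFAULT_REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "abts": (7.4, 11.7),
    "frap": (14.0, 47.7),
    "dpph": (11.4, 30.2),
}

# FRAP standard curve: absorbance = slope * concentration(uM) + intercept,
# validated over 50-500 uM.
FRAP_SLOPE = 0.0019
FRAP_INTERCEPT = 0.0044
FRAP_VALID_RANGE_UM = (50.0, 500.0)


@dataclass
class AssayMeasurement:
    """One radical-scavenging assay reading.

    a0: absorbance of the blank (radical working solution alone);
    a1: absorbance of sample mixed with the working solution;
    a2: absorbance of the sample solution without the working solution
    (corrects for the sample's own colour).
    """

    a0: float
    a1: float
    a2: float

    def __post_init__(self):
        if not self.a0 > 0:
            raise InvalidMeasurementError(f"blank absorbance a0 must be positive, got {self.a0}")


def clearance_capacity(m: AssayMeasurement) -> float:
    """Radical clearance capacity in percent: 100*(a0 - (a1 - a2))/a0.

    The formula is returned unclamped; pathological absorbances can produce
    values outside [0, 100].
    """
    return 100.0 * (m.a0 - (m.a1 - m.a2)) / m.a0


class FrapResult(NamedTuple):
    concentration_um: float
    out_of_range: bool


def frap_concentration(absorbance: float) -> FrapResult:
    """Invert the FRAP standard curve to a FeSO4-equivalent concentration.

    Returns the concentration in uM and a flag set when the result lies
    outside the curve's validated 50-500 uM range.
    """
    conc = (absorbance - FRAP_INTERCEPT) / FRAP_SLOPE
    lo, hi = FRAP_VALID_RANGE_UM
    eps = 1e-9 * hi  # keep float noise at the endpoints from flagging
    return FrapResult(conc, bool(conc < lo - eps or conc > hi + eps))


@dataclass
class ComponentSpec:
    """One latent chemical component: its absorption bands and its linear
    contribution to each antioxidant assay."""

    band_centers: list[float]
    band_widths: list[float]
    band_heights: list[float]
    conc_low: float = 0.2
    conc_high: float = 1.0
    effect_abts: float = 1.0
    effect_frap: float = 1.0
    effect_dpph: float = 1.0

    def __post_init__(self):
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_heights)):
            raise ValueError("band_centers, band_widths, band_heights must have equal length")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        if not self.conc_low < self.conc_high:
            raise ValueError("conc_low must be below conc_high")

    def effect(self, analyte: str) -> float:
        return {"abts": self.effect_abts, "frap": self.effect_frap, "dpph": self.effect_dpph}[
            analyte
        ]

    def profile(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Unit-concentration absorbance profile: sum of Gaussian bands."""
        lam = np.asarray(wavelengths_nm)
        out = np.zeros_like(lam, dtype=float)
        for c, w, h in zip(self.band_centers, self.band_widths, self.band_heights):
            out += h * np.exp(-((lam - c) ** 2) / (2.0 * w * w))
        return out


def default_components() -> list[ComponentSpec]:
    """Latent components of a powdered-herb NIR spectrum.

    Three assay-active constituents sit at the canonical hydrogen-bond band
    positions with fairly narrow bands: component 1 carries the O-H bands
    (polysaccharide-like), component 2 the C-H overtone bands
    (phenolic-like), component 3 the C-H/CH2 combination bands. All three
    contribute to every assay with different weights.

    The remainder of the matrix is assay-inert: a broad, strong residual-
    moisture component overlapping the O-H region, plus ten minor
    constituents (protein/cellulose/lipid-like) with two narrow bands each
    at fixed quasi-random positions kept clear of the informative band
    centers. These vary independently of the assays and give the spectra a
    nuisance subspace of realistic rank — the reason full-spectrum models
    are fragile and wavelength selection pays off.
    """
    _inert = dict(conc_low=0.2, conc_high=1.0, effect_abts=0.0, effect_frap=0.0, effect_dpph=0.0)
    return [
        ComponentSpec(
            band_centers=[1440.0, 1940.0],
            band_widths=[18.0, 22.0],
            band_heights=[0.50, 0.60],
            effect_abts=1.0,
            effect_frap=1.0,
            effect_dpph=1.0,
        ),
        ComponentSpec(
            band_centers=[1210.0, 1730.0],
            band_widths=[15.0, 18.0],
            band_heights=[0.40, 0.50],
            effect_abts=0.8,
            effect_frap=1.5,
            effect_dpph=0.6,
        ),
        ComponentSpec(
            band_centers=[2280.0, 2330.0],
            band_widths=[14.0, 14.0],
            band_heights=[0.45, 0.45],
            effect_abts=0.5,
            effect_frap=0.7,
            effect_dpph=1.2,
        ),
        # residual moisture: broad O-H bands shadowing component 1
        ComponentSpec([1410.0, 1905.0], [70.0, 80.0], [1.00, 1.30],
                      conc_low=0.3, conc_high=1.2,
                      effect_abts=0.0, effect_frap=0.0, effect_dpph=0.0),
        # minor inert constituents (fixed quasi-random layout)
        ComponentSpec([2008.9, 1116.4], [19.4, 18.7], [0.37, 0.62], **_inert),
        ComponentSpec([2204.1, 1387.8], [31.5, 19.3], [0.60, 0.55], **_inert),
        ComponentSpec([1369.3, 2174.8], [25.4, 19.6], [0.37, 0.50], **_inert),
        ComponentSpec([1867.5, 1301.8], [15.3, 24.4], [0.59, 0.67], **_inert),
        ComponentSpec([1349.8, 2077.7], [20.6, 30.9], [0.65, 0.42], **_inert),
        ComponentSpec([1788.4, 1141.5], [26.7, 19.8], [0.61, 0.37], **_inert),
        ComponentSpec([1060.6, 1086.2], [24.9, 24.4], [0.35, 0.40], **_inert),
        ComponentSpec([1044.5, 1581.1], [26.5, 23.5], [0.63, 0.55], **_inert),
        ComponentSpec([2191.7, 2117.5], [26.3, 23.7], [0.46, 0.31], **_inert),
        ComponentSpec([2383.5, 1658.2], [24.7, 25.4], [0.46, 0.53], **_inert),
    ]


def default_grid() -> np.ndarray:
    """1557-point axis, even in wavenumber from 10000 to 4000 cm^-1
    (FT-instrument convention), stored ascending in nm (1000-2500 nm)."""
    wavenumbers = np.linspace(10000.0, 4000.0, 1557)
    return 1.0e7 / wavenumbers  # ascending in nm


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults give 111 samples on the 1557-point 1000-2500 nm grid. Scatter
    is a per-sample smooth multiplicative field: a flat gain (sd 10%) times
    a low-order wavelength dependence (linear tilt and curvature terms,
    each sd 0.8 across the axis) — the standard particle-size behaviour of
    diffuse reflectance, which SNV/MSC remove only approximately — plus a
    0.05 AU additive offset and 5 mAU white detector noise. Assay noise is
    3% of each analyte's range.
    """

    n_samples: int = 111
    wavelengths_nm: np.ndarray = field(default_factory=default_grid)
    components: list[ComponentSpec] = field(default_factory=default_components)
    scatter_mult_sd: float = 0.10
    scatter_tilt_sd: float = 0.8
    scatter_curve_sd: float = 0.8
    scatter_add_sd: float = 0.05
    noise_sd: float = 0.005
    assay_noise_sd: float = 0.03
    compositional: bool = True
    reference_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_RANGES)
    )
    seed: int = 0

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        for name in (
            "scatter_mult_sd",
            "scatter_tilt_sd",
            "scatter_curve_sd",
            "scatter_add_sd",
            "noise_sd",
            "assay_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.components:
            raise ValueError("at least one component is required")
        lo, hi = self.wavelengths_nm.min(), self.wavelengths_nm.max()
        for k, comp in enumerate(self.components):
            for c in comp.band_centers:
                if not (lo <= c <= hi):
                    raise ValueError(
                        f"component {k}: band center {c} nm outside grid span [{lo:.1f}, {hi:.1f}]"
                    )


@dataclass
class GroundTruth:
    """What the generator actually planted: per-component informative
    wavelength indices (within +/- 2 band widths of each band center, for
    components with a nonzero effect on at least one analyte), the union of
    those indices, the latent concentration matrix, and the seed/config."""

    informative_indices: list[int]
    indices_by_component: list[list[int]]
    concentrations: np.ndarray
    seed: int
    config: SyntheticConfig


def _component_indices(comp: ComponentSpec, wavelengths_nm: np.ndarray) -> list[int]:
    mask = np.zeros(wavelengths_nm.size, dtype=bool)
    for c, w in zip(comp.band_centers, comp.band_widths):
        mask |= np.abs(wavelengths_nm - c) <= 2.0 * w
    return np.flatnonzero(mask).tolist()


# Keep rescaled signal this many assay-noise SDs clear of the range edges.
_RANGE_MARGIN_SDS = 4.0


def simulate(config: SyntheticConfig) -> tuple[SpectraSet, ReferenceTable, GroundTruth]:
    """Draw one synthetic data set.

    Spectra: absorbance(lam) = sum_c conc_c * profile_c(lam), scaled by the
    per-sample scatter field (1 + m_i) * (1 + t_i*u(lam) + c_i*q(lam)) with
    m_i ~ N(0, scatter_mult_sd), t_i ~ N(0, scatter_tilt_sd), c_i ~
    N(0, scatter_curve_sd) and u, q the centered linear/quadratic axis
    terms, plus offset o_i ~ N(0, scatter_add_sd), plus white noise
    N(0, noise_sd). Concentrations are normalized to sum 1 by default
    (per-mass composition). Reference values: an affine map of the
    effect-weighted concentration sums into each analyte's range (leaving a
    margin of 4 assay-noise SDs at either edge), plus
    N(0, assay_noise_sd * range) noise. Deterministic for a fixed config
    (including seed).
    """
    rng = np.random.default_rng(config.seed)
    lam = config.wavelengths_nm
    n, p = config.n_samples, lam.size

    profiles = np.stack([comp.profile(lam) for comp in config.components])  # (k, p)
    conc = np.stack(
        [rng.uniform(c.conc_low, c.conc_high, size=n) for c in config.components], axis=1
    )  # (n, k)
    if config.compositional and len(config.components) > 1:
        # per-mass composition: assays respond to relative make-up, while
        # absolute signal magnitude is a packing/path-length artifact that
        # the multiplicative scatter gain models (and SNV/MSC remove)
        conc = conc / conc.sum(axis=1, keepdims=True)
    clean = conc @ profiles

    gains = 1.0 + rng.normal(0.0, config.scatter_mult_sd, size=n)
    # smooth wavelength dependence of the scatter gain (centered linear and
    # quadratic terms over the axis span)
    u = (lam - lam.mean()) / (lam.max() - lam.min())
    q = u * u - np.mean(u * u)
    tilt = rng.normal(0.0, config.scatter_tilt_sd, size=n)
    curve = rng.normal(0.0, config.scatter_curve_sd, size=n)
    scatter_field = gains[:, None] * (1.0 + tilt[:, None] * u[None, :] + curve[:, None] * q[None, :])
    offsets = rng.normal(0.0, config.scatter_add_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))
    absorbance = clean * scatter_field + offsets[:, None] + noise

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    spectra = SpectraSet(lam, absorbance, sample_ids)

    ref_cols: dict[str, np.ndarray] = {}
    for analyte, (lo, hi) in config.reference_ranges.items():
        effects = np.array([c.effect(analyte) for c in config.components])
        z = conc @ effects
        span = hi - lo
        noise_sd = config.assay_noise_sd * span
        margin = _RANGE_MARGIN_SDS * noise_sd
        z_lo, z_hi = z.min(), z.max()
        if z_hi > z_lo:
            scaled = lo + margin + (z - z_lo) * (span - 2 * margin) / (z_hi - z_lo)
        else:  # all effects zero: park the signal mid-range
            scaled = np.full_like(z, (lo + hi) / 2.0)
        ref_cols[analyte] = scaled + rng.normal(0.0, noise_sd, size=n)

    references = ReferenceTable(sample_ids, **ref_cols)

    by_comp = [
        _component_indices(c, lam)
        for c in config.components
        if any(c.effect(a) != 0.0 for a in ("abts", "frap", "dpph"))
    ]
    union = sorted(set().union(*by_comp)) if by_comp else []
    truth = GroundTruth(
        informative_indices=union,
        indices_by_component=by_comp,
        concentrations=conc,
        seed=config.seed,
        config=config,
    )
    return spectra, references, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar recording what was planted (for audit, not modelling)."""
    cfg = asdict(truth.config)
    cfg["wavelengths_nm"] = np.asarray(cfg["wavelengths_nm"]).tolist()
    payload = {
        "seed": truth.seed,
        "informative_indices": list(map(int, truth.informative_indices)),
        "indices_by_component": [list(map(int, ix)) for ix in truth.indices_by_component],
        "concentrations": np.asarray(truth.concentrations).tolist(),
        "config": cfg,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
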
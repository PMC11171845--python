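"""End-to-end study orchestration.

The full workflow mirrors how NIR calibrations for antioxidant activity
are actually built: simulate (or load) spectra and reference values,
screen for spectral outliers by Mahalanobis distance, split samples with
Kennard-Stone, compare pretreatments under Full-spectrum PLS, then compare
wavelength selectors (Full vs GA vs CARS) on the winning pretreatment, and
report the whole validation battery per model.

Determinism: a single master seed fans out (via ``numpy.random.SeedSequence``)
to the generator, the selectors and the y-randomization draws; two runs
with the same config produce identical reports.

Leakage discipline: every statistic that parametrizes a transform (MSC
reference, centering means, CV folds, wavelength choice) is computed on
calibration samples only. The Kennard-Stone split itself operates on
spectra of all samples — it must, to partition them — but never sees
reference values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from nircal.io import (
    SpectraSet,
    ReferenceTable,
    read_spectra,
    read_references,
    write_report,
)
from nircal.synthetic import SyntheticConfig, simulate
from nircal.preprocess import Preprocessor, PreprocessorSpec
from nircal.sampling import kennard_stone, mahalanobis_outliers
from nircal.pls import fit_pls, cross_validate
from nircal.selection import CarsConfig, GaConfig, cars_select, ga_select
from nircal.validation import EvaluationReport, evaluate_model

logger = logging.getLogger(__name__)

DEFAULT_PRETREATMENTS = ("raw", "d1_sg", "msc", "snv", "smoothing")
ANALYTES = ("abts", "frap", "dpph")


@dataclass
class PipelineConfig:
    """Everything one study run needs. With no input paths, data come from
    the synthetic generator at the master seed."""

    spectra_path: Optional[str] = None
    reference_path: Optional[str] = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess_methods: tuple = DEFAULT_PRETREATMENTS
    analytes: tuple = ANALYTES
    calibration_fraction: float = 2.0 / 3.0
    calibration_size: Optional[int] = None
    outlier_rule: str = "chauvenet"
    variance_kept: float = 0.99
    max_lvs: int = 20
    cv_folds: int = 10
    selection_pretreatment: str = "snv"
    ga: GaConfig = field(default_factory=GaConfig)
    cars: CarsConfig = field(default_factory=CarsConfig)
    n_perm: int = 25
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if not self.analytes:
            raise ValueError("at least one analyte required")
        if not self.preprocess_methods:
            raise ValueError("at least one pretreatment required")


def _stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(4)
    names = ("simulate", "ga", "cars", "yrand")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def load_inputs(config: PipelineConfig):
    """Return (spectra, references, ground_truth_or_None)."""
    if config.spectra_path is not None:
        spectra = read_spectra(config.spectra_path)
        refs = read_references(config.reference_path)
        return spectra, refs, None
    seeds = _stage_seeds(config.seed)
    syn = replace(config.synthetic, seed=seeds["simulate"])
    return simulate(syn)


def fit_calibration(
    cal_spectra: SpectraSet,
    y: np.ndarray,
    spec: PreprocessorSpec,
    wavelength_indices: Optional[np.ndarray] = None,
    max_lvs: int = 20,
    cv_folds: int = 10,
):
    """Freeze the pretreatment on the calibration set, cross-validate the
    latent-variable count, and fit the final model. Returns (model, cv)."""
    preproc = Preprocessor(spec).fit(cal_spectra)
    X = preproc.transform(cal_spectra).absorbance
    if wavelength_indices is None:
        wavelength_indices = np.arange(X.shape[1])
    Xs = X[:, wavelength_indices]
    n = Xs.shape[0]
    cap = max(1, min(max_lvs, Xs.shape[1], n - 1 - int(np.ceil(n / cv_folds))))
    cv = cross_validate(Xs, y, max_lvs=cap, folds=min(cv_folds, n))
    model = fit_pls(
        Xs,
        y,
        cv.chosen_lvs,
        wavelength_indices=wavelength_indices,
        axis_nm=cal_spectra.wavelengths_nm,
        preprocessor=preproc,
    )
    return model, cv


def _split(config: PipelineConfig, spectra: SpectraSet, method: str):
    """Kennard-Stone split on spectra preprocessed by ``method`` (split
    distances only; modelling refits the pretreatment on calibration)."""
    pre = Preprocessor(PreprocessorSpec(method=method)).fit(spectra)
    return kennard_stone(
        pre.transform(spectra),
        calibration_fraction=config.calibration_fraction,
        calibration_size=config.calibration_size,
    )


def screen_outliers(config: PipelineConfig, spectra: SpectraSet):
    """Outlier report plus the spectra with flagged samples removed."""
    report = mahalanobis_outliers(
        spectra, variance_kept=config.variance_kept, rule=config.outlier_rule
    )
    if report.flagged:
        logger.info("removing %d flagged sample(s): %s", len(report.flagged), report.flagged)
        keep = [s for s in spectra.sample_ids if s not in set(report.flagged)]
        spectra = spectra.subset_samples(keep)
    return report, spectra


def _evaluate_cell(
    config: PipelineConfig,
    spectra: SpectraSet,
    references: ReferenceTable,
    analyte: str,
    pretreatment: str,
    method_label: str,
    wavelength_indices=None,
    yrand_seed: int = 0,
    split=None,
) -> EvaluationReport:
    if split is None:
        split = _split(config, spectra, pretreatment)
    cal = spectra.subset_samples(split.calibration_ids)
    pred = spectra.subset_samples(split.prediction_ids)
    y_cal = references.subset_samples(split.calibration_ids).values(analyte)
    y_pred = references.subset_samples(split.prediction_ids).values(analyte)
    model, cv = fit_calibration(
        cal,
        y_cal,
        PreprocessorSpec(method=pretreatment),
        wavelength_indices=wavelength_indices,
        max_lvs=config.max_lvs,
        cv_folds=config.cv_folds,
    )
    return evaluate_model(
        model,
        cal,
        y_cal,
        pred,
        y_pred,
        cv,
        analyte=analyte,
        method=method_label,
        n_perm=config.n_perm,
        seed=yrand_seed,
    )


def run_pretreatment_comparison(config: PipelineConfig, data=None) -> dict:
    """Full-spectrum PLS for every (pretreatment, analyte) cell.

    Returns {"reports": [...], "table": DataFrame, "best": {analyte:
    method}, "failed": [...]} where best is the gate-compliant
    pretreatment with minimal RMSECV per analyte.
    """
    spectra, references, _ = data if data is not None else load_inputs(config)
    _, spectra = screen_outliers(config, spectra)
    seeds = _stage_seeds(config.seed)

    reports, failed = [], []
    for method in config.preprocess_methods:
        for analyte in config.analytes:
            try:
                rep = _evaluate_cell(
                    config,
                    spectra,
                    references,
                    analyte,
                    method,
                    method_label=method,
                    yrand_seed=seeds["yrand"],
                )
                reports.append(rep)
            except Exception as exc:  # keep the grid running
                logger.error("cell (%s, %s) failed: %s", method, analyte, exc)
                failed.append({"method": method, "analyte": analyte, "error": str(exc)})

    table = pd.DataFrame([r.table_row() for r in reports])
    best = {}
    for analyte in config.analytes:
        cands = [r for r in reports if r.analyte == analyte]
        compliant = [r for r in cands if all(r.gates.values())] or cands
        if compliant:
            winner = min(compliant, key=lambda r: r.rmsecv)
            best[analyte] = winner.method
            logger.info("best pretreatment for %s: %s (RMSECV %.4g)",
                        analyte, winner.method, winner.rmsecv)
    return {"reports": reports, "table": table, "best": best, "failed": failed}


def run_selector_comparison(config: PipelineConfig, data=None) -> dict:
    """Full-PLS vs GA-PLS vs CARS-PLS per analyte on one pretreatment.

    All three selectors share the same Kennard-Stone split (computed on the
    chosen pretreatment). The summary includes the percent RMSEP decrease
    of CARS-PLS relative to Full-PLS per analyte.
    """
    spectra, references, _ = data if data is not None else load_inputs(config)
    _, spectra = screen_outliers(config, spectra)
    seeds = _stage_seeds(config.seed)
    pretreatment = config.selection_pretreatment
    split = _split(config, spectra, pretreatment)

    cal = spectra.subset_samples(split.calibration_ids)
    pre = Preprocessor(PreprocessorSpec(method=pretreatment)).fit(cal)
    X_cal = pre.transform(cal).absorbance

    reports, selections, failed = [], {}, []
    for analyte in config.analytes:
        y_cal = references.subset_samples(split.calibration_ids).values(analyte)
        cells = {"full_pls": None}
        try:
            ga_res = ga_select(X_cal, y_cal, replace(config.ga, seed=seeds["ga"]))
            selections[(analyte, "ga_pls")] = ga_res
            cells["ga_pls"] = ga_res.selected_indices
        except Exception as exc:
            logger.error("GA selection failed for %s: %s", analyte, exc)
            failed.append({"method": "ga_pls", "analyte": analyte, "error": str(exc)})
        try:
            cars_res = cars_select(X_cal, y_cal, replace(config.cars, seed=seeds["cars"]))
            selections[(analyte, "cars_pls")] = cars_res
            cells["cars_pls"] = cars_res.selected_indices
        except Exception as exc:
            logger.error("CARS selection failed for %s: %s", analyte, exc)
            failed.append({"method": "cars_pls", "analyte": analyte, "error": str(exc)})

        for label, indices in cells.items():
            try:
                rep = _evaluate_cell(
                    config,
                    spectra,
                    references,
                    analyte,
                    pretreatment,
                    method_label=label,
                    wavelength_indices=indices,
                    yrand_seed=seeds["yrand"],
                    split=split,
                )
                reports.append(rep)
            except Exception as exc:
                logger.error("cell (%s, %s) failed: %s", label, analyte, exc)
                failed.append({"method": label, "analyte": analyte, "error": str(exc)})

    table = pd.DataFrame([r.table_row() for r in reports])
    summary = {}
    for analyte in config.analytes:
        by_method = {r.method: r for r in reports if r.analyte == analyte}
        if "full_pls" in by_method and "cars_pls" in by_method:
            summary[analyte] = {
                "rmsep_full": by_method["full_pls"].rmsep,
                "rmsep_cars": by_method["cars_pls"].rmsep,
                "pct_rmsep_decrease": pct_rmsep_decrease(
                    by_method["full_pls"].rmsep, by_method["cars_pls"].rmsep
                ),
            }
    return {
        "reports": reports,
        "table": table,
        "selections": selections,
        "split": split,
        "summary": summary,
        "failed": failed,
    }


def pct_rmsep_decrease(rmsep_full: float, rmsep_reduced: float) -> float:
    """Percent decrease of RMSEP relative to the full-spectrum model:
    100 * (RMSEP_full - RMSEP_reduced) / RMSEP_full."""
    if rmsep_full <= 0:
        raise ValueError("RMSEP of the full model must be positive")
    return 100.0 * (rmsep_full - rmsep_reduced) / rmsep_full


def run_full_study(config: PipelineConfig) -> dict:
    """Pretreatment comparison, then selector comparison, with all outputs
    optionally written under ``config.output_dir``."""
    data = load_inputs(config)
    outlier_report, _ = screen_outliers(config, data[0])
    pretreat = run_pretreatment_comparison(config, data=data)
    selector = run_selector_comparison(config, data=data)

    bundle = {
        "outliers": outlier_report,
        "pretreatment": pretreat,
        "selector": selector,
    }
    if config.output_dir is not None:
        _write_bundle(config, bundle)
    return bundle


def _write_bundle(config: PipelineConfig, bundle: dict) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    (out / "traces").mkdir(exist_ok=True)

    bundle["pretreatment"]["table"].to_csv(out / "pretreatment_comparison.csv", index=False)
    bundle["selector"]["table"].to_csv(out / "selector_comparison.csv", index=False)
    for rep in bundle["pretreatment"]["reports"] + bundle["selector"]["reports"]:
        write_report(rep, out / "reports" / f"{rep.analyte}_{rep.method}.json")
    for (analyte, method), sel in bundle["selector"]["selections"].items():
        sel.trace_table().to_csv(out / "traces" / f"{analyte}_{method}.csv", index=False)
        with open(out / "traces" / f"{analyte}_{method}_selection.json", "w") as fh:
            json.dump(sel.to_dict(), fh, indent=1)

    manifest = {
        "seed": config.seed,
        "stage_seeds": _stage_seeds(config.seed),
        "analytes": list(config.analytes),
        "preprocess_methods": list(config.preprocess_methods),
        "selection_pretreatment": config.selection_pretreatment,
        "best_pretreatment": bundle["pretreatment"]["best"],
        "outliers_flagged": bundle["outliers"].flagged,
        "summary": bundle["selector"]["summary"],
        "failed": bundle["pretreatment"]["failed"] + bundle["selector"]["failed"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
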
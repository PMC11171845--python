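"""Containers and text-format I/O for spectra, reference tables, models
and evaluation reports.

On-disk conventions
-------------------
Spectra: plain CSV, UTF-8, '.' decimal separator. Header cell (0,0) is the
literal ``sample_id``; the remaining header cells are wavelengths in nm
(written with at least 4 decimals). Each following row is one sample.

Reference tables: CSV with a ``sample_id`` column and any subset of the
columns ``abts`` (percent clearance), ``frap`` (umol/L FeSO4 equivalents)
and ``dpph`` (percent clearance).

Models and reports: JSON envelopes with numeric arrays as lists. Files
whose name ends in ``.gz`` are transparently gzip-compressed.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from nircal.errors import FormatError

logger = logging.getLogger(__name__)

_REFERENCE_COLUMNS = ("abts", "frap", "dpph")


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


@dataclass
class SpectraSet:
    """A wavelength axis, an absorbance matrix and sample identifiers.

    ``wavelengths_nm`` is strictly ascending; ``absorbance`` has one row per
    sample and one column per wavelength; ``sample_ids`` are unique strings.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.wavelengths_nm.ndim != 1:
            raise FormatError("wavelength axis must be one-dimensional")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise FormatError("wavelength axis must be strictly ascending")
        n, p = self.absorbance.shape
        if p != self.wavelengths_nm.size:
            raise FormatError(
                f"absorbance has {p} columns but axis has {self.wavelengths_nm.size} points"
            )
        if n != len(self.sample_ids):
            raise FormatError(
                f"absorbance has {n} rows but {len(self.sample_ids)} sample ids given"
            )
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise FormatError(f"duplicate sample id(s): {sorted(dupes)}")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise FormatError("non-finite wavelength value")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise FormatError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]}, column {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset_samples(self, ids: list[str]) -> "SpectraSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SpectraSet(self.wavelengths_nm, self.absorbance[rows], list(ids))

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.wavelengths_nm, matrix, list(self.sample_ids))


@dataclass
class ReferenceTable:
    """Per-sample antioxidant reference values.

    Any subset of the three analytes may be present; absent analytes are
    ``None``. Units: ABTS and DPPH in percent clearance, FRAP in umol/L.
    """

    sample_ids: list[str]
    abts: Optional[np.ndarray] = None
    frap: Optional[np.ndarray] = None
    dpph: Optional[np.ndarray] = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise FormatError(f"duplicate sample id(s): {sorted(dupes)}")
        for name in _REFERENCE_COLUMNS:
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.sample_ids),):
                    raise FormatError(f"column {name} has wrong length")
                if not np.all(np.isfinite(v)):
                    raise FormatError(f"non-finite value in column {name}")
                setattr(self, name, v)

    @property
    def analytes(self) -> list[str]:
        return [c for c in _REFERENCE_COLUMNS if getattr(self, c) is not None]

    def values(self, analyte: str) -> np.ndarray:
        v = getattr(self, analyte, None)
        if v is None:
            raise KeyError(f"analyte {analyte!r} absent from reference table")
        return v

    def subset_samples(self, ids: list[str]) -> "ReferenceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        kw = {
            c: getattr(self, c)[rows] for c in _REFERENCE_COLUMNS if getattr(self, c) is not None
        }
        return ReferenceTable(list(ids), **kw)


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for s in ids:
        if s in seen:
            dup.add(s)
        seen.add(s)
    return dup


# ---------------------------------------------------------------------------
# spectra CSV


def write_spectra(spectra: SpectraSet, path) -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{w:.6f}" for w in spectra.wavelengths_nm],
    )
    with _open_text(path, "w") as fh:
        df.to_csv(fh, lineterminator="\n")


def read_spectra(path) -> SpectraSet:
    """Read a spectra CSV; columns are permuted to an ascending axis if the
    file stores wavelengths descending (a notice is logged)."""
    try:
        with _open_text(path, "r") as fh:
            df = pd.read_csv(fh, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse spectra file {path}: {exc}") from exc
    if df.index.name != "sample_id":
        raise FormatError(
            f"header cell (0,0) must be 'sample_id', found {df.index.name!r}"
        )
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header in {path}: {exc}") from exc
    matrix = df.to_numpy()
    if matrix.dtype.kind not in "fiu":
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise FormatError(
                    f"non-numeric absorbance at sample {row!r}, wavelength {col}"
                )
        matrix = matrix.astype(float)
    if np.all(np.diff(wavelengths) < 0):
        logger.info("wavelength axis in %s is descending; re-sorting ascending", path)
        order = np.argsort(wavelengths)
        wavelengths, matrix = wavelengths[order], matrix[:, order]
    return SpectraSet(wavelengths, matrix, [str(s) for s in df.index])


# ---------------------------------------------------------------------------
# reference-table CSV


def write_references(table: ReferenceTable, path) -> None:
    data = {"sample_id": table.sample_ids}
    for c in table.analytes:
        data[c] = getattr(table, c)
    with _open_text(path, "w") as fh:
        pd.DataFrame(data).to_csv(fh, index=False, lineterminator="\n")


def read_references(path) -> ReferenceTable:
    try:
        with _open_text(path, "r") as fh:
            df = pd.read_csv(fh)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse reference file {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise FormatError("reference file lacks a 'sample_id' column")
    kw = {}
    for c in _REFERENCE_COLUMNS:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                row = df.loc[vals.isna(), "sample_id"].iloc[0]
                raise FormatError(f"non-numeric {c} value at sample {row!r}")
            kw[c] = vals.to_numpy()
    return ReferenceTable([str(s) for s in df["sample_id"]], **kw)


# ---------------------------------------------------------------------------
# model / report JSON

_FORMAT_VERSION = 1


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_model(model, path, metadata: Optional[dict] = None) -> None:
    """Serialize a fitted PLS model (with its frozen preprocessor and
    wavelength subset) so prediction is reproducible from the file alone."""
    envelope = {
        "format": "nircal-pls-model",
        "format_version": _FORMAT_VERSION,
        "metadata": _jsonify(metadata or {}),
        "model": _jsonify(model.to_dict()),
    }
    with _open_text(path, "w") as fh:
        json.dump(envelope, fh, indent=1)


def load_model(path):
    from nircal.pls import PLSModel  # deferred: avoid import cycle

    with _open_text(path, "r") as fh:
        envelope = json.load(fh)
    if envelope.get("format") != "nircal-pls-model":
        raise FormatError(f"{path} is not a model file")
    return PLSModel.from_dict(envelope["model"])


def write_report(report, path, metadata: Optional[dict] = None) -> None:
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    envelope = {
        "format": "nircal-report",
        "format_version": _FORMAT_VERSION,
        "metadata": _jsonify(metadata or {}),
        "report": _jsonify(payload),
    }
    with _open_text(path, "w") as fh:
        json.dump(envelope, fh, indent=1)


def read_report(path) -> dict:
    with _open_text(path, "r") as fh:
        envelope = json.load(fh)
    if envelope.get("format") != "nircal-report":
        raise FormatError(f"{path} is not a report file")
    return envelope["report"]
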
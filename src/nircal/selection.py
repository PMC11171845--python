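"""Wavelength selection: competitive adaptive reweighted sampling (CARS)
and genetic-algorithm (GA) selection, both with PLS cross-validated error
as the figure of merit.

CARS runs N Monte Carlo iterations. Each iteration fits a PLS model on a
random 80% row subsample restricted to the currently active wavelengths,
then prunes the active set in two stages driven by the normalized absolute
regression coefficients w_j = |b_j| / sum|b|:

* a forced cut by the exponentially decreasing function (EDF), which keeps
  only the ceil(r_i * p) largest-|b| wavelengths, where
  r_i = a * exp(-k*i), a = (p/2)^(1/(N-1)), k = ln(p/2)/(N-1) —
  so r_1 = 1 (nothing removed at the first run) and ceil(r_N * p) = 2;
* adaptive reweighted sampling (ARS): the same number of draws with
  replacement, with probability w_j, keeping the unique drawn wavelengths
  (a stochastic competition that favours large coefficients).

The subset whose 10-fold RMSECV on the full calibration set is smallest
over the N runs is returned.

The GA evolves binary chromosomes over wavelengths (tournament selection,
single-point crossover, bit-flip mutation, one elite). Many short
independent runs are performed; a wavelength's *frequency* is the number
of runs whose best chromosome contains it, and wavelengths at or above a
frequency threshold are selected. Because the GA is stochastic, the whole
procedure is repeated several times and the repeat with the median final
RMSECV is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from nircal.errors import SelectionError
from nircal.pls import _nipals, _coefficients, cross_validate

logger = logging.getLogger(__name__)


@dataclass
class CarsConfig:
    n_runs: int = 100
    sample_fraction: float = 0.8
    cv_folds: int = 10
    max_lvs: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.sample_fraction < 1:
            raise ValueError("sample_fraction must be in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("n_runs must be at least 2")


@dataclass
class GaConfig:
    n_runs: int = 100
    population: int = 30
    generations: int = 100
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    frequency_threshold: int = 4
    n_repeats: int = 5
    init_prob: float = 0.10
    cv_folds: int = 10
    max_lvs: int = 20
    window: int = 1  # >1: mean-bin this many adjacent wavelengths before the GA
    seed: int = 0

    def __post_init__(self):
        if self.frequency_threshold < 0:
            raise ValueError("frequency_threshold must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for name in ("crossover_prob", "mutation_prob", "init_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_runs, self.population, self.generations, self.n_repeats) < 1:
            raise ValueError("n_runs, population, generations, n_repeats must be >= 1")


@dataclass
class SelectionResult:
    selected_indices: np.ndarray
    method: str  # "ga" | "cars"
    rmsecv_of_subset: float
    n_lvs: int
    trace: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def trace_table(self) -> pd.DataFrame:
        """Per-run trace as a flat table (CARS: run/kept_count/rmsecv;
        GA: wavelength index/frequency), suitable for CSV export."""
        if self.method == "cars":
            return pd.DataFrame(
                {
                    "run": np.arange(1, len(self.trace["kept_counts"]) + 1),
                    "kept_count": self.trace["kept_counts"],
                    "edf_count": self.trace["edf_counts"],
                    "rmsecv": self.trace["rmsecv_by_run"],
                }
            )
        return pd.DataFrame(
            {
                "wavelength_index": np.arange(len(self.trace["frequencies"])),
                "frequency": self.trace["frequencies"],
            }
        )

    def to_dict(self) -> dict:
        d = {
            "selected_indices": np.asarray(self.selected_indices).tolist(),
            "method": self.method,
            "rmsecv_of_subset": float(self.rmsecv_of_subset),
            "n_lvs": int(self.n_lvs),
            "seed": self.seed,
        }
        d["trace"] = {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.trace.items()
            if k != "coefficient_path"
        }
        return d


# ---------------------------------------------------------------------------
# CARS


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Fraction of wavelengths force-retained at Monte Carlo run i.

    r_i = a * exp(-k*i) with a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1),
    so that r_1 = 1 and r_N = 2/p.
    """
    if not 1 <= i <= n_runs:
        raise ValueError(f"run index {i} not in [1, {n_runs}]")
    if p < 2:
        raise ValueError("need at least 2 variables")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p / 2.0) / (n_runs - 1)
    return a * math.exp(-k * i)


def edf_kept_count(i: int, n_runs: int, p: int) -> int:
    """Number of wavelengths force-retained at run i: ceil(r_i * p)."""
    return int(math.ceil(edf_ratio(i, n_runs, p) * p))


def _fit_coefficients(X, y, max_lvs, cv_folds, rng_seed=None):
    """Inner PLS fit: pick LVs by cross-validation, return the regression
    vector at that LV count (fit on all given rows)."""
    n, p = X.shape
    cap = min(max_lvs, n - 1 - math.ceil(n / cv_folds), p)
    cap = max(cap, 1)
    cv = cross_validate(X, y, max_lvs=cap, folds=min(cv_folds, n))
    x_mean = X.mean(axis=0)
    W, P, q = _nipals(X - x_mean, y - y.mean(), cv.chosen_lvs)
    k = W.shape[1]
    return _coefficients(W, P, q, k), cv

def cars_select(X: np.ndarray, y: np.ndarray, config: CarsConfig) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the columns of X.

    Returns the active wavelength set of the Monte Carlo run with the
    smallest full-calibration 10-fold RMSECV, together with the per-run
    traces (kept counts, RMSECV, full-length coefficient path).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError(f"CARS needs at least 10 samples, got {n}")
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")

    rng = np.random.default_rng(config.seed)
    m = int(math.floor(config.sample_fraction * n))

    active = np.arange(p)
    kept_counts: list[int] = []
    edf_counts: list[int] = []
    rmsecv_by_run: list[float] = []
    lvs_by_run: list[int] = []
    active_by_run: list[np.ndarray] = []
    coefficient_path = np.zeros((config.n_runs, p))

    for i in range(1, config.n_runs + 1):
        rows = rng.choice(n, size=m, replace=False)
        b, _ = _fit_coefficients(
            X[np.ix_(rows, active)], y[rows], config.max_lvs, config.cv_folds
        )
        coefficient_path[i - 1, active] = b
        absb = np.abs(b)
        total = absb.sum()
        if total == 0:
            logger.warning("CARS run %d: all coefficients zero; stopping early", i)
            break

        target = min(edf_kept_count(i, config.n_runs, p), active.size)
        edf_counts.append(target)
        # forced EDF cut: top-|b| wavelengths (stable order for determinism)
        order = np.argsort(-absb, kind="stable")[:target]
        kept = active[order]
        w = absb[order] / absb[order].sum()
        # ARS: p competitive draws with replacement, unique survivors --
        # with few retained variables nearly all survive, so the active-set
        # size tracks the EDF schedule after the sharp early drop
        drawn = rng.choice(kept, size=p, replace=True, p=w)
        active = np.unique(drawn)
        kept_counts.append(int(active.size))

        if active.size < 2:
            # collapsed active set: terminate; earlier runs stay candidates
            logger.warning("CARS run %d: active set collapsed below 2 variables", i)
            kept_counts.pop()
            edf_counts.pop()
            break

        cap = min(config.max_lvs, active.size)
        cv = cross_validate(X[:, active], y, max_lvs=cap, folds=min(config.cv_folds, n))
        rmsecv_by_run.append(cv.rmsecv)
        lvs_by_run.append(cv.chosen_lvs)
        active_by_run.append(active.copy())

    if not active_by_run:
        raise SelectionError("CARS produced no usable subsets")
    best = int(np.argmin(rmsecv_by_run))
    selected = np.sort(active_by_run[best])
    return SelectionResult(
        selected_indices=selected,
        method="cars",
        rmsecv_of_subset=float(rmsecv_by_run[best]),
        n_lvs=int(lvs_by_run[best]),
        trace={
            "kept_counts": np.array(kept_counts),
            "edf_counts": np.array(edf_counts),
            "rmsecv_by_run": np.array(rmsecv_by_run),
            "lvs_by_run": np.array(lvs_by_run),
            "best_run": best + 1,
            "coefficient_path": coefficient_path[: len(kept_counts)],
        },
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# GA


def _ga_fitness(chrom: np.ndarray, X, y, config: GaConfig, cache: dict) -> float:
    """Negative RMSECV of a PLS model on the chromosome's wavelengths."""
    key = chrom.tobytes()
    if key in cache:
        return cache[key]
    idx = np.flatnonzero(chrom)
    if idx.size == 0:
        fit = -np.inf
    else:
        n = X.shape[0]
        cap = min(config.max_lvs, idx.size, n - 1 - math.ceil(n / config.cv_folds))
        cap = max(cap, 1)
        cv = cross_validate(X[:, idx], y, max_lvs=cap, folds=min(config.cv_folds, n))
        fit = -cv.rmsecv
    cache[key] = fit
    return fit


def _ga_single_run(X, y, config: GaConfig, rng: np.random.Generator) -> np.ndarray:
    """One GA run; returns the best chromosome seen."""
    n, p = X.shape
    pop = rng.random((config.population, p)) < config.init_prob
    # guarantee non-empty chromosomes
    for c in pop:
        if not c.any():
            c[rng.integers(p)] = True
    cache: dict = {}
    fitness = np.array([_ga_fitness(c, X, y, config, cache) for c in pop])
    best_idx = int(np.argmax(fitness))
    best_chrom, best_fit = pop[best_idx].copy(), fitness[best_idx]

    for _ in range(config.generations):
        new_pop = [best_chrom.copy()]  # elitism
        while len(new_pop) < config.population:
            parents = []
            for _ in range(2):  # size-2 tournament
                a, b = rng.integers(config.population, size=2)
                parents.append(pop[a] if fitness[a] >= fitness[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_prob and p > 1:
                cut = int(rng.integers(1, p))
                c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
            for c in (c1, c2):
                flips = rng.random(p) < config.mutation_prob
                c ^= flips
                if not c.any():
                    c[rng.integers(p)] = True
                new_pop.append(c)
        pop = np.array(new_pop[: config.population])
        fitness = np.array([_ga_fitness(c, X, y, config, cache) for c in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = fitness[gen_best]
            best_chrom = pop[gen_best].copy()
    return best_chrom


def ga_select(X: np.ndarray, y: np.ndarray, config: GaConfig) -> SelectionResult:
    """Genetic-algorithm wavelength selection with run-frequency voting.

    ``n_runs`` independent GA runs each contribute their best chromosome;
    wavelengths present in at least ``frequency_threshold`` best
    chromosomes are selected. The whole procedure is repeated
    ``n_repeats`` times and the repeat with the median final RMSECV is
    returned (even repeat counts use the lower median).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p_orig = X.shape
    if n < 10:
        raise ValueError(f"GA selection needs at least 10 samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")

    # optional mean-binning: the GA then works on window averages and its
    # selection expands back to the member wavelengths
    if config.window > 1:
        n_bins = int(math.ceil(p_orig / config.window))
        bins = [
            np.arange(b * config.window, min((b + 1) * config.window, p_orig))
            for b in range(n_bins)
        ]
        X = np.column_stack([X[:, ix].mean(axis=1) for ix in bins])
    else:
        bins = None
    p = X.shape[1]

    master = np.random.default_rng(config.seed)
    repeat_results = []
    for _ in range(config.n_repeats):
        rng = np.random.default_rng(master.integers(2**31))
        freq = np.zeros(p, dtype=int)
        for _ in range(config.n_runs):
            best = _ga_single_run(X, y, config, rng)
            freq += best
        selected = np.flatnonzero(freq >= config.frequency_threshold)
        if selected.size == 0:
            raise SelectionError(
                f"no wavelength reached frequency {config.frequency_threshold} over "
                f"{config.n_runs} runs; decrease frequency_threshold"
            )
        cap = min(config.max_lvs, selected.size, n - 1 - math.ceil(n / config.cv_folds))
        cv = cross_validate(
            X[:, selected], y, max_lvs=max(cap, 1), folds=min(config.cv_folds, n)
        )
        repeat_results.append((cv.rmsecv, cv.chosen_lvs, selected, freq))

    rmsecvs = np.array([r[0] for r in repeat_results])
    median_pos = int(np.argsort(rmsecvs, kind="stable")[(len(rmsecvs) - 1) // 2])
    rmsecv, n_lvs, selected, freq = repeat_results[median_pos]
    if bins is not None:
        # expand bin selection back to the member wavelengths
        selected = np.concatenate([bins[j] for j in selected])
        expanded = np.zeros(p_orig, dtype=int)
        for j, ix in enumerate(bins):
            expanded[ix] = freq[j]
        freq = expanded
    return SelectionResult(
        selected_indices=selected,
        method="ga",
        rmsecv_of_subset=float(rmsecv),
        n_lvs=int(n_lvs),
        trace={
            "frequencies": freq,
            "rmsecv_by_repeat": rmsecvs,
            "chosen_repeat": median_pos,
            "frequency_threshold": config.frequency_threshold,
        },
        seed=config.seed,
    )
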
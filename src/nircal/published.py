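"""Published benchmark metrics from the NIR antioxidant calibration study
of *Dendrobium officinale* that this package's synthetic generator
emulates (111 samples, 1557-variable spectra, ABTS/FRAP/DPPH responses).

The study's raw spectra were never deposited, so its headline model errors
cannot be recomputed; what *can* be recomputed exactly is the arithmetic
its comparison tables report: the chance-correlation statistic cR2P from
each row's (R2C, R2rand) pair, and the percent RMSEP decrease of CARS-PLS
relative to Full-PLS. The values below are the printed table rows, kept
here as regression-test inputs for that arithmetic.

Each pretreatment row: (R2C, R2rand, cR2P printed). Each selector row:
(R2C, R2rand, cR2P printed, RMSEP).
"""

from __future__ import annotations

# pretreatment comparison: analyte -> method -> (r2_c, r2_rand, cr2p_printed)
PRETREATMENT_TABLE: dict[str, dict[str, tuple[float, float, float]]] = {
    "abts": {
        "raw": (0.806, 0.024, 0.79),
        "d1_sg": (0.749, 0.049, 0.72),
        "msc": (0.837, 0.050, 0.81),
        "snv": (0.836, 0.042, 0.81),
        "smoothing": (0.801, 0.017, 0.79),
    },
    "frap": {
        "raw": (0.855, 0.101, 0.80),
        "d1_sg": (0.974, 0.126, 0.91),
        "msc": (0.888, 0.004, 0.89),
        "snv": (0.888, 0.127, 0.82),
        "smoothing": (0.851, 0.075, 0.81),
    },
    "dpph": {
        "raw": (0.813, 0.075, 0.77),
        "d1_sg": (0.833, 0.125, 0.77),
        "msc": (0.814, 0.060, 0.78),
        "snv": (0.831, 0.017, 0.82),
        "smoothing": (0.806, 0.100, 0.75),
    },
}

# selector comparison: analyte -> method -> (r2_c, r2_rand, cr2p_printed, rmsep)
SELECTOR_TABLE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "abts": {
        "full_pls": (0.836, 0.042, 0.81, 0.57),
        "ga_pls": (0.852, 0.214, 0.74, 0.49),
        "cars_pls": (0.865, 0.164, 0.78, 0.51),
    },
    "frap": {
        "full_pls": (0.888, 0.127, 0.82, 2.23),
        "ga_pls": (0.872, 0.058, 0.84, 2.31),
        "cars_pls": (0.917, 0.082, 0.88, 2.05),
    },
    "dpph": {
        "full_pls": (0.831, 0.017, 0.82, 1.91),
        "ga_pls": (0.866, 0.019, 0.86, 2.11),
        "cars_pls": (0.866, 0.038, 0.85, 1.76),
    },
}

# reported percent decrease of CARS-PLS RMSEP vs Full-PLS, per analyte
REPORTED_RMSEP_DECREASE_PCT: dict[str, float] = {
    "abts": 10.53,
    "frap": 8.07,
    "dpph": 7.85,
}


def iter_cr2p_rows():
    """Yield (table, analyte, method, r2_c, r2_rand, cr2p_printed) for
    every row of both comparison tables."""
    for analyte, methods in PRETREATMENT_TABLE.items():
        for method, (r2c, r2rand, printed) in methods.items():
            yield "pretreatment", analyte, method, r2c, r2rand, printed
    for analyte, methods in SELECTOR_TABLE.items():
        for method, (r2c, r2rand, printed, _) in methods.items():
            yield "selector", analyte, method, r2c, r2rand, printed
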
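#!/usr/bin/env python
"""Generate the default synthetic study data set (111 powdered-herb NIR
spectra, 1557 wavelengths, ABTS/FRAP/DPPH references) and write it to
results/data/ together with the planted ground truth."""

from pathlib import Path

import numpy as np

from nircal.io import write_references, write_spectra
from nircal.synthetic import SyntheticConfig, simulate, write_ground_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=seed)
    spectra, refs, truth = simulate(cfg)

    write_spectra(spectra, OUT / "spectra.csv.gz")
    write_references(refs, OUT / "references.csv")
    write_ground_truth(truth, OUT / "ground_truth.json")

    print(f"spectra: {spectra.n_samples} samples x {spectra.n_wavelengths} wavelengths "
          f"({spectra.wavelengths_nm[0]:.0f}-{spectra.wavelengths_nm[-1]:.0f} nm)")
    for analyte in refs.analytes:
        v = refs.values(analyte)
        print(f"  {analyte}: mean {v.mean():.1f}, sd {v.std(ddof=1):.1f}, "
              f"range {v.min():.1f}-{v.max():.1f}")
    n_info = len(truth.informative_indices)
    print(f"planted informative wavelengths: {n_info} "
          f"({100 * n_info / spectra.n_wavelengths:.1f}% of the axis) across "
          f"{len(truth.indices_by_component)} assay-active components")


if __name__ == "__main__":
    main()
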
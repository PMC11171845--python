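#!/usr/bin/env python
"""Screen the data set for abnormal spectra (Mahalanobis distance in PCA
score space, Chauvenet rule) and partition it 2:1 into calibration and
prediction sets with Kennard-Stone. Writes results/outliers.json and
results/split.json."""

import json
from pathlib import Path

from nircal.pipeline import PipelineConfig, load_inputs, screen_outliers, _split

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    spectra, refs, _ = load_inputs(cfg)

    report, spectra = screen_outliers(cfg, spectra)
    (RESULTS / "outliers.json").write_text(json.dumps(report.to_dict(), indent=1))
    print(f"outlier screening: {report.subspace_dims}-dim PCA subspace, "
          f"rule={report.rule}, flagged={report.flagged or 'none'}")

    split = _split(cfg, spectra, cfg.selection_pretreatment)
    (RESULTS / "split.json").write_text(json.dumps(split.to_dict(), indent=1))
    print(f"Kennard-Stone split: {len(split.calibration_ids)} calibration / "
          f"{len(split.prediction_ids)} prediction")
    for analyte in refs.analytes:
        cal = refs.subset_samples(split.calibration_ids).values(analyte)
        pred = refs.subset_samples(split.prediction_ids).values(analyte)
        print(f"  {analyte}: cal mean {cal.mean():.1f} (sd {cal.std(ddof=1):.1f}) | "
              f"pred mean {pred.mean():.1f} (sd {pred.std(ddof=1):.1f})")


if __name__ == "__main__":
    main()
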
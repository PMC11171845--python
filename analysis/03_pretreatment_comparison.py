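#!/usr/bin/env python
"""Compare the five spectral pretreatments (raw, 1D+SG, MSC, SNV, SG
smoothing) under full-spectrum PLS for each antioxidant analyte, and pick
the winner by cross-validated error. Writes
results/pretreatment_comparison.csv."""

from pathlib import Path

from nircal.pipeline import PipelineConfig, run_pretreatment_comparison

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(analytes=("abts", "frap", "dpph"), n_perm=25, seed=seed)
    out = run_pretreatment_comparison(cfg)
    out["table"].to_csv(RESULTS / "pretreatment_comparison.csv", index=False)
    print(out["table"].to_string(index=False))
    print()
    for analyte, method in out["best"].items():
        print(f"best pretreatment for {analyte}: {method}")
    if out["failed"]:
        print("failed cells:", out["failed"])


if __name__ == "__main__":
    main()
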
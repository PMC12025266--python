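#!/usr/bin/env python
"""Simulate the two-group cohort and quantify 13C enrichments.

Generates the default synthetic study — 8 control and 8 ischemic mice,
six brain regions each, paired reference/edited scans per sample — runs
the processing chain (auto phase, masked-ALS baseline, TMSP calibration),
integrates the 18 catalogued metabolite windows and writes the enrichment
table, the TMSP steady-state QC table and the generating ground truth
under results/.

Run from the repository root:  python analysis/01_simulate_and_quantify.py
"""

from pathlib import Path

from pocenmr.pipeline import run_study
from pocenmr.synthdata import CohortDesign

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    res = run_study(CohortDesign(seed=SEED))
    res["table"].to_csv(OUT / "enrichment_table.csv", index=False)
    res["ground_truth"].to_csv(OUT / "ground_truth.csv", index=False)
    res["qc"].to_csv(OUT / "tmsp_qc.csv", index=False)

    qc = res["qc"]["steady_ratio"]
    merged = res["table"].merge(
        res["ground_truth"],
        on=["mouse_id", "group", "region", "metabolite"])
    err = (merged["enrichment_pct_x"] - merged["enrichment_pct_y"]).abs()
    print(f"quantified {len(res['qc'])} samples x 18 windows")
    print(f"TMSP steady-state QC: {qc.mean():.3f} +/- {qc.std(ddof=1):.3f} "
          "(generator: 1.100 +/- 0.030)")
    print(f"median |recovered - true| enrichment: {err.median():.2f} pp")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
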
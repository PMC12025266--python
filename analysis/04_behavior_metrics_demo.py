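#!/usr/bin/env python
"""Worked example of the behavioral/electrophysiological formulas.

Builds small synthetic trial tables and an ECoG-like test signal, then
computes the discrimination index (with the 10 s exclusion rule), corner
turn percentages, 60 s-censored beam times, Welch band powers and the
JC-1 membrane-potential index. Writes results/behavior_metrics.json.
"""

import json
from pathlib import Path

import numpy as np

from pocenmr import studymetrics

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(1)

    nor = [(30.0, 20.0), (18.0, 16.0), (6.0, 3.0), (40.0, 10.0)]
    di = [studymetrics.discrimination_index(a, b) for a, b in nor]
    turns = ["left"] * 7 + ["right"] * 2 + ["invalid"]
    left, right, n_valid = studymetrics.turn_ratio(turns)
    beams = [studymetrics.censor_beam_time(t) for t in (12.3, 48.0, 75.0)]
    beams.append(studymetrics.censor_beam_time(fell=True))

    fs = 256.0
    t = np.arange(0, 30.0, 1 / fs)
    sig = (np.sin(2 * np.pi * 6.0 * t)          # theta-band oscillation
           + 0.3 * np.sin(2 * np.pi * 2.0 * t)  # delta component
           + 0.1 * rng.normal(size=len(t)))     # broadband noise
    powers = studymetrics.band_powers(sig, fs)

    out = {
        "discrimination_index": [
            {"t_novel": a, "t_familiar": b, "di": r.di, "excluded": r.excluded}
            for (a, b), r in zip(nor, di)],
        "turn_ratio": {"left_pct": left, "right_pct": right,
                       "n_valid": n_valid},
        "beam_times_s": [{"seconds": b.seconds, "censored": b.censored}
                         for b in beams],
        "band_power": powers,
        "mito_potential_index": studymetrics.mito_potential_index(590.0, 295.0),
    }
    (OUT / "behavior_metrics.json").write_text(json.dumps(out, indent=1))

    dom = max(powers, key=powers.get)
    print(f"DI values: {[None if r.excluded else round(r.di, 3) for r in di]} "
          "(third trial excluded: 9 s < 10 s exploration)")
    print(f"turn ratio: {left:.0f}/{right:.0f} over {n_valid} valid trials")
    print(f"beam times: {[b.seconds for b in beams]} s")
    print(f"dominant band: {dom} "
          f"({powers[dom] / sum(powers.values()):.0%} of total power)")
    print(f"membrane-potential index (590/295): "
          f"{out['mito_potential_index']:.1f}")


if __name__ == "__main__":
    main()
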
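#!/usr/bin/env python
"""Spearman correlation networks per group, with FDR retention and hubs.

Reads results/enrichment_table.csv (run 01 first), builds the
inter-metabolite network for each group over the 48 (mouse x region)
observations, applies the |rho| > 0.8 and BH q < 0.01 retention rule,
scores hub strength, and writes edge lists, GraphML exports and hub
tables under results/.
"""

from pathlib import Path

import pandas as pd

from pocenmr import netcorr
from pocenmr.synthdata import GROUPS, REGIONS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "enrichment_table.csv")
    for group in GROUPS:
        edges = netcorr.metabolite_network(table, group)
        edges.to_csv(OUT / f"network_{group}.csv", index=False)
        netcorr.to_graphml(edges, OUT / f"network_{group}.graphml")
        hubs = netcorr.hub_scores(edges)
        hubs.to_csv(OUT / f"hubs_{group}.csv", index=False)
        kept = edges[edges["retained"]]
        print(f"{group}: {len(kept)} of {len(edges)} metabolite pairs retained")
        if not kept.empty:
            top = kept.reindex(kept["rho"].abs().sort_values(
                ascending=False).index).iloc[0]
            print(f"  strongest edge: {top.item_a}-{top.item_b} "
                  f"rho={top.rho:.2f} q={top.q_fdr:.2g}")

    # regional coordination of lactate in the control group
    reg = netcorr.regional_network(table, "Lactate", "control")
    reg.to_csv(OUT / "regional_lactate_control.csv", index=False)
    print(f"lactate regional pairs tested: {len(reg)} over regions {REGIONS}")


if __name__ == "__main__":
    main()
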
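# pocenmr

¹³C isotopic-enrichment analysis for paired reference/edited (POCE)
¹H NMR spectra of brain tissue extracts, with a synthetic-cohort
simulator that makes every stage testable without any experimental data.

## The problem

Proton-observed carbon-edited (POCE) NMR measures how much of a
metabolite pool carries a ¹³C label from an infused tracer such as
[3-¹³C]glucose. Each sample yields two 1D spectra: a *reference* scan
recording the total proton signal (¹²C + ¹³C) and an *edited* scan
isolating protons bound to ¹³C. For a metabolite with catalogued
chemical-shift window *W*, the fractional enrichment is

```
enrichment (%) = 100 x ∫_W edited / ∫_W reference   ( = [¹³C] / [¹³C + ¹²C] x 100 )
```

Applied across six brain regions (FC, OC, TC, STR, HP, THA) in control
and ischemic mice, these enrichments quantify how cerebral ischemia
depletes central-carbon metabolism — most metabolites fall 30–50%, GABA
by about half — while lactate and the related three-carbon species
(alanine, aspartate, N-acetylaspartate) hold their enrichment and their
mutual rank correlations (Spearman |ρ| > 0.8 at BH-FDR q < 0.01),
marking them as the compensatory substrates of the ischemic brain.

The package implements that full analysis as a tested pipeline:

| module | role |
|---|---|
| `pocenmr.synthdata` | frequency-domain Lorentzian spectrum simulator + Gaussian-copula cohort generator with known ground truth |
| `pocenmr.specproc` | zero-order phasing (auto via negative-intensity minimisation), signal-masked ALS baseline, TMSP chemical-shift calibration |
| `pocenmr.quant` | Table-style window integration, enrichment ratios, TMSP loading normalisation + steady-state QC |
| `pocenmr.netcorr` | inter-metabolite and inter-regional Spearman networks, BH FDR, hub scores, GraphML export |
| `pocenmr.cohortstats` | percent depletion with bootstrap CIs, Lilliefors normality screen, ANOVA + Tukey HSD |
| `pocenmr.studymetrics` | discrimination index, corner-test turn ratio, 60 s beam censoring, Welch ECoG band power, JC-1 ΔΨm index |
| `pocenmr.pipeline`, `pocenmr.cli` | end-to-end drivers and the `pocenmr` command-line interface |

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_and_quantify.py
python analysis/02_metabolite_networks.py
python analysis/03_group_statistics.py
python analysis/04_behavior_metrics_demo.py
```

Output of the first three (seed 1):

```
quantified 96 samples x 18 windows
TMSP steady-state QC: 1.106 +/- 0.041 (generator: 1.100 +/- 0.030)
median |recovered - true| enrichment: 0.95 pp

control: 1 of 136 metabolite pairs retained
  strongest edge: Ala-Lactate rho=0.82 q=1.3e-10
ischemia: 1 of 136 metabolite pairs retained
  strongest edge: Ala-Lactate rho=0.82 q=9.7e-11

normality screen passed for 18 of 18 control metabolites
depleted metabolites: reduction 27-47% (all ANOVA p < 0.05: True)
spared (Lac/Ala/Asp3/NAA): 4.5% worst-case shift
GABA reduction: 45.9% (generator effect: 50%)
```

Reading: the pipeline recovers per-sample enrichments to about one
percentage point through rendered spectra, noise and preprocessing; the
TMSP QC ratio scatters around the generator's isotopic steady-state
value; the strict |ρ| > 0.8 & q < 0.01 rule keeps the planted
lactate–alanine edge and essentially nothing else; and the group
comparison separates the 30–50%-depleted metabolites from the spared
three-carbon set.

The same pipeline is scriptable (`pocenmr demo --seed 1 --outdir out/`)
or usable as a library:

```python
from pocenmr import CohortDesign, run_study, metabolite_network

res = run_study(CohortDesign(seed=1))
edges = metabolite_network(res["table"], "control")
print(edges[edges.retained])
```

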
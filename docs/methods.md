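# Methods

## Spectrum model

Spectra are simulated directly in the frequency domain. Each metabolite
contributes an absorption-mode Lorentzian at its catalogued chemical
shift with half-width-at-half-maximum γ (default 0.005 ppm, ≈2.5 Hz at
500 MHz) and area proportional to its abundance; the edited scan scales
each area by the ¹³C enrichment fraction, and the internal standard TMSP
appears in both scans with edited/reference ratio equal to a per-sample
steady-state factor. A zero-order phase error φ₀ mixes absorption and
dispersion lineshapes as cos φ₀·A + sin φ₀·D; a polynomial baseline in
ppm and i.i.d. Gaussian noise are added last. There is no FID/FFT round
trip: simulating in the frequency domain keeps every window integral
available in closed form,

∫ₐᵇ A = area/π · [arctan((b−x₀)/γ) − arctan((a−x₀)/γ)],

which the tests use as an independent oracle against the trapezoidal
integrator. The raw two-subscan POCE subtraction is not modelled — the
edited scan is generated as the post-subtraction ¹³C-only spectrum.
¹³C satellite splitting (J-doublets) is off by default and available via
`AcquisitionParams.satellite_split`, which renders the labelled fraction
as two half-area peaks at ±split/2; the catalogued windows are wide
relative to typical J, so window integrals are unchanged.

Default grid: 16384 points over 20 ppm starting at −2 ppm (≈0.0012
ppm/point, ≥4 points per γ); 65536 points reproduces the full
acquisition density. Default noise: sd = 1/(100·π·γ) intensity units,
i.e. SNR ≈ 100 for a unit-abundance peak; the acquisition hardware's
true noise is not stated anywhere, so this is a configurable choice,
not an inferred value.

## Cohort generator

A cohort is 2 groups × n mice (default 8) × 6 regions. Per sample, a
latent Gaussian vector with a specified correlation matrix (the copula)
is transformed through a mean-preserving lognormal, value =
mean·exp(σz − σ²/2) with σ² = ln(1 + CV²), so the group mean is hit
exactly in expectation, scatter is multiplicative at the given CV
(default 0.1), and the copula's rank correlations survive the monotone
transform. Ischemia multiplies enrichment means by per-metabolite
depletion factors: 0.5 for GABA3/GABA4 (the ~50% effect), values in
[0.5, 0.7] for the other depleted species so recovered reductions land
in the reported 30–50% band, and 1.0 for the spared set
{Lactate, Ala, Asp3, NAA}. The default copula carries a 0.9 block over
the spared set (identity elsewhere), emulating the retained coordination
among the three-carbon metabolites; independent-metabolite nulls are
obtained by passing an identity matrix. The TMSP steady-state factor is
drawn Normal(1.10, 0.03) per sample. Non-PSD copulas raise; a
`repair_non_psd` flag projects onto the nearest PSD correlation matrix.

Baseline abundances and control enrichments are not published anywhere;
they are fixed once at plausible [3-¹³C]glucose labelling values (high
on the glycolytic end, intermediate on the glutamate pool, low on
inositols). Spectrally adjacent metabolites are given similar
enrichments deliberately: windows printed as adjacent ranges receive
genuine Lorentzian tail bleed from their neighbours (the simulator
reproduces it, the catalogue integrates "as printed" without
apportioning), and harmonised neighbour enrichments keep that cross-talk
from biasing the ratio — with the defaults, noise-free end-to-end
recovery is within 0.5 percentage points for all 17 metabolites.

## Processing chain

Order: phase → baseline → calibrate, mirroring operator practice.

*Phasing.* The dispersion partner is reconstructed with an FFT Hilbert
transform after removing the straight line through the spectrum's end
points (a baseline offset otherwise becomes spurious edge dispersion)
and zero-padding one signal-length per side (suppressing circular
wrap-around of slowly decaying dispersion tails). `phi0="auto"` scans
[−π, π) at 0.5° minimising the sum of squared negative intensities on a
line-detrended copy of the spectrum — without detrending, a positive
baseline lifts the dispersion wings above zero and the objective
degenerates into a flat plateau — then refines by golden section to
0.01°. Round-trip accuracy is ≤0.01 rad for injected φ₀ up to ~1.5 rad
on the default axis. Residual window-integral distortion grows with
|φ₀| (Hilbert reconstruction of a truncated multi-peak spectrum is not
exact); beyond |φ₀| ≈ 0.2 rad wide windows in crowded regions can exceed
2% error, a known limitation.

*Baseline.* Eilers asymmetric least squares (second-difference penalty
λ, asymmetry p = 0.001, 10 reweighting iterations) solved with a banded
Cholesky. Two departures from the plainest ALS, both forced by measured
failure modes: (i) λ defaults to 1e8 in grid-index units — at 1e5 the
fit bends into 4-point-wide peaks and clips ~5% of their area, violating
the 1%-restoration contract; (ii) the fit is *signal-masked*: a very
stiff rough pass (λ ≥ 1e12, which cannot absorb the pedestal formed by
overlapping Lorentzian tails between clustered peaks) defines a
residual threshold max(5·noise sd, 2·10⁻⁴·max), points above it are
masked out (with slight dilation) and the final ALS interpolates the
baseline beneath peak clusters instead of through them. Because the
asymmetric fit otherwise settles on the *lower envelope* of the noise
band, the corrected spectrum is re-levelled by the median of its
signal-free residuals; on noiseless input this re-levelling is skipped,
making an all-zero spectrum an exact fixed point.

*Calibration.* The ppm axis is shifted uniformly so the TMSP apex
(3-point parabolic sub-grid interpolation) sits at its catalogued
0.004 ppm center — the catalogue is followed literally rather than the
conventional 0.000 ppm. Intensities are untouched. Shifts beyond
0.05 ppm (the stated tolerance for matching known chemical shifts)
warn but do not fail. First-order (frequency-dependent) phase
correction is not implemented; the simulator injects only φ₀.

## Quantification

Windows are integrated by trapezoid with linearly interpolated partial
end bins (exactly additive over partitions, sign-preserving).
Enrichment = 100·edited/reference per window; non-positive reference
integrals yield explicit missing values, and ratios outside [0, 100]
are flagged but never clipped (clipping would bias group means — TMSP
itself sits near 110% by design). TMSP normalisation divides each
sample's integrals by its loading factor (sample TMSP reference
integral over the cohort mean), which cancels in the enrichment ratio
but standardises absolute areas; the per-sample edited/reference TMSP
ratio is reported as a QC table whose mean and sd recover the
generator's steady-state distribution.

## Correlation networks

Spearman ρ per unordered pair over (mouse × region) observations within
a group (pairwise-complete; a mouse-level pooling variant sits behind
`pool_mice`). Two-sided p-values use the exact permutation null of ρ
(enumerated once per n and cached) for n ≤ 9 without ties, else the
t approximation. Benjamini–Hochberg runs jointly over all tested pairs;
an edge is retained only when both |ρ| > 0.8 and q < 0.01, strictly —
the conjunctive reading of the stated rule. Pearson is available as a
flag for comparison with normality-assuming analyses but is not the
default. Regional matrices correlate one metabolite across mice for
each of the 15 region pairs with BH within that family. Hub scores are
retained-edge degree and summed |ρ| strength; ties rank alphabetically,
so empty networks (all-zero scores, warned) carry no hub information.

## Group statistics

Percent reduction = 100·(1 − mean_ischemia/mean_control) with a seeded
bias-corrected percentile bootstrap (default 2000 resamples) for the
95% CI; the interval is widened minimally if the BC quantiles would
exclude the point estimate. Normality screening uses the Lilliefors
variant of Kolmogorov–Smirnov (parameters estimated from the sample) at
α = 0.05. One-way ANOVA (scipy) with Tukey HSD per pair; Tukey is
always computed but flagged "reported" only when the omnibus p < 0.05.
Across the metabolite grid, BH-adjusted q-values accompany raw p.

## Behavioral / electrophysiological formulas

Discrimination index (T_novel − T_familiar)/(T_novel + T_familiar) with
the <10 s total-exploration exclusion returning an explicit excluded
marker; corner-test left/right percentages over caller-declared valid
trials (validity beyond the >90° rotation criterion is not further
specified, so it is an input); beam-walk times censored at 60 s with
falls and timeouts recorded as 60 s and the censoring flag retained;
band power via Welch (2 s Hann segments, 50% overlap — an estimator
choice, none is prescribed) integrated over Delta 0.5–4, Theta 4–8,
Alpha 8–13, Beta 13–30, Gamma 30–100 Hz by the same trapezoid helper,
so a shared band edge receives half weight on each side and partitions
are exactly additive; ΔΨm index = JC-1 aggregate/monomer fluorescence.

## What the synthetic data do and do not show

The generator reproduces the study's *statistical* structure — group
effects, regional layout, rank-correlation structure, internal-standard
behaviour, multiplicative biological scatter, additive spectral noise —
on idealised Lorentzian spectra. It does not model lineshape distortion,
first-order phase, solvent or macromolecule background, J-multiplets
(beyond the optional satellite flag), relaxation/NOE area biases, or
isotopomer-resolved label propagation. Passing recovery tests therefore
demonstrates that the pipeline is correct and well-calibrated under its
stated model, not that the acquisition chain of a real spectrometer is
free of systematics.

## Problem sizes

Test and acceptance runs use the study's design sizes (8 mice/group,
6 regions, 48 observations per group) with spectra at the 16384-point
desk grid or a 4096-point window covering −0.4 to 4.6 ppm at identical
grid density; Monte-Carlo checks use 100–200 seeds at the
ground-truth level (no spectra) and 1000 replicates for the ANOVA
calibration. These sizes were chosen so the whole suite runs in a few
minutes while keeping every statistical tolerance meaningful.
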
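"""Synthetic paired reference/edited spectra and multi-region cohorts.

The generator emulates the statistical structure of a two-group
(control vs ischemia) mouse study read out by proton-observed
carbon-edited (POCE) NMR:

* each sample is a brain-region extract with per-metabolite abundances
  and 13C enrichment fractions (the ground truth the pipeline must
  recover);
* the *reference* scan carries every metabolite as an absorption-mode
  Lorentzian at its catalogued chemical shift with area proportional to
  abundance; the *edited* scan carries area proportional to
  abundance x enrichment (the post-subtraction 13C-only spectrum);
* the internal standard TMSP appears in both scans, its edited/reference
  area ratio set by a per-sample steady-state factor (isotopic
  equilibrium of the tracer);
* ischemia multiplies enrichment means by per-metabolite depletion
  factors, with a spared set (lactate and related three-carbon species)
  left at factor 1.0;
* inter-metabolite rank correlation is injected through a Gaussian
  copula; biological scatter is multiplicative lognormal at a given CV;
  spectral noise is additive Gaussian.

Spectra are simulated directly in the frequency domain with closed-form
lineshapes (no FID/FFT round trip), so every window integral has an
analytic arctan expression usable as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectrum import Spectrum1D
from .windows import MetaboliteWindow, window_map

REGIONS = ("FC", "OC", "TC", "STR", "HP", "THA")
GROUPS = ("control", "ischemia")
TMSP = "TMSP"

#: 17 quantified 13C-labelled species (numeric suffix = labelled carbon).
DEFAULT_METABOLITES = (
    "Lactate", "GABA3", "GABA4", "NAA", "NAAG", "Glu3", "Glu4", "Gln4",
    "Glx2", "Glx3", "Suc", "Asp3", "m-Ins", "m-Ins2", "m-Ins3", "tau", "Ala",
)

#: Mean tissue abundances (arbitrary units) — order-of-magnitude realistic
#: relative pool sizes, not concentrations.
DEFAULT_AMOUNTS = {
    "Lactate": 1.2, "GABA3": 0.7, "GABA4": 0.7, "NAA": 1.0, "NAAG": 0.8,
    "Glu3": 1.2, "Glu4": 1.2, "Gln4": 0.8, "Glx2": 1.0, "Glx3": 1.0,
    "Suc": 0.4, "Asp3": 0.8, "m-Ins": 0.9, "m-Ins2": 0.9, "m-Ins3": 0.9,
    "tau": 1.1, "Ala": 0.6,
}

#: Control-group mean 13C enrichment fractions from [3-13C]glucose:
#: highest on the glycolytic end (lactate, alanine), intermediate on the
#: glutamate/glutamine pool, low on inositols (slow turnover).
DEFAULT_ENRICHMENTS = {
    "Lactate": 0.35, "GABA3": 0.20, "GABA4": 0.20, "NAA": 0.18, "NAAG": 0.20,
    "Glu3": 0.22, "Glu4": 0.24, "Gln4": 0.22, "Glx2": 0.20, "Glx3": 0.20,
    "Suc": 0.18, "Asp3": 0.20, "m-Ins": 0.10, "m-Ins2": 0.10, "m-Ins3": 0.10,
    "tau": 0.15, "Ala": 0.33,
}

#: Metabolites whose enrichment the ischemic insult spares (factor 1.0).
DEFAULT_SPARED = ("Lactate", "Ala", "Asp3", "NAA")

#: Multiplicative ischemia effect on enrichment means. Non-spared factors
#: sit in [0.5, 0.7] so recovered reductions land in the 30-50% range;
#: GABA at 0.5 (~50% depletion at both labelled carbons).
DEFAULT_DEPLETION = {
    "Lactate": 1.0, "Ala": 1.0, "Asp3": 1.0, "NAA": 1.0,
    "GABA3": 0.5, "GABA4": 0.5,
    "NAAG": 0.6, "Glu3": 0.6, "Glu4": 0.6, "Gln4": 0.65,
    "Glx2": 0.6, "Glx3": 0.6, "Suc": 0.55,
    "m-Ins": 0.65, "m-Ins2": 0.65, "m-Ins3": 0.65, "tau": 0.7,
}

#: TMSP steady-state edited/reference ratio distribution (QC target).
DEFAULT_TMSP_STEADY_MEAN = 1.10
DEFAULT_TMSP_STEADY_SD = 0.03

#: Latent rank correlation among the spared three-carbon metabolites —
#: the coordination that survives the insult in both groups.
SPARED_CORR = 0.9


def default_copula(metabolites=DEFAULT_METABOLITES,
                   spared=DEFAULT_SPARED) -> np.ndarray:
    """Default latent correlation: a 0.9 block over the spared set,
    identity elsewhere."""
    m = len(metabolites)
    c = np.eye(m)
    idx = [metabolites.index(s) for s in spared if s in metabolites]
    for i in idx:
        for j in idx:
            if i != j:
                c[i, j] = SPARED_CORR
    return c


# ---------------------------------------------------------------------------
# closed-form lineshapes (the analytic oracle)
# ---------------------------------------------------------------------------

def lorentzian_absorption(x, x0: float, gamma: float, area: float = 1.0):
    """Absorption-mode Lorentzian of total area ``area`` and HWHM ``gamma``."""
    return area / math.pi * gamma / ((x - x0) ** 2 + gamma**2)


def lorentzian_dispersion(x, x0: float, gamma: float, area: float = 1.0):
    """Dispersion-mode partner (Hilbert transform of the absorption mode)."""
    return area / math.pi * (x - x0) / ((x - x0) ** 2 + gamma**2)


def lorentzian_window_integral(x0: float, gamma: float, lo: float, hi: float,
                               area: float = 1.0) -> float:
    """Exact integral of the absorption Lorentzian over [lo, hi]:
    area/pi * [arctan((hi-x0)/gamma) - arctan((lo-x0)/gamma)].
    """
    return area / math.pi * (
        math.atan((hi - x0) / gamma) - math.atan((lo - x0) / gamma)
    )


# ---------------------------------------------------------------------------
# acquisition and sample descriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """Frequency-domain acquisition/rendering parameters.

    Defaults: 20 ppm spectral width at 16384 points (desk scale; set
    ``n_points=65536`` for the full acquisition grid), Lorentzian HWHM
    0.005 ppm, additive noise sd giving SNR ~ 100 for a unit-amount peak.
    ``baseline_coeffs`` are ascending-power polynomial coefficients in ppm.
    ``satellite_split`` (ppm), when positive, renders the 13C-bound
    fraction as a doublet of half-area peaks at center +/- split/2.
    """

    spectral_width: float = 20.0
    n_points: int = 16384
    ppm_start: float = -2.0
    linewidth_gamma: float = 0.005
    noise_sd: float = 1.0 / (100.0 * math.pi * 0.005)
    phase0: float = 0.0
    baseline_coeffs: tuple = ()
    satellite_split: float = 0.0

    def __post_init__(self) -> None:
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be > 0")
        if self.n_points < 1024:
            raise ValueError("n_points must be >= 1024")
        if self.linewidth_gamma <= 0:
            raise ValueError("linewidth_gamma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.ppm_start, self.ppm_start + self.spectral_width,
                           self.n_points)


@dataclass
class SampleSpec:
    """Ground-truth description of one tissue-extract sample."""

    mouse_id: str
    group: str
    region: str
    amounts: dict
    enrichments: dict
    tmsp_amount: float = 1.0
    tmsp_steady_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.tmsp_amount <= 0:
            raise ValueError("tmsp_amount must be > 0")
        for m, a in self.amounts.items():
            if a < 0:
                raise ValueError(f"negative amount for {m}")
        for m, e in self.enrichments.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"enrichment for {m} outside [0, 1]: {e}")


# ---------------------------------------------------------------------------
# spectrum pair simulation
# ---------------------------------------------------------------------------

def _render(ppm: np.ndarray, components: list[tuple[float, float]], gamma: float,
            phase0: float) -> np.ndarray:
    """Sum of Lorentzians (center, area), phase-mixed by phase0."""
    y = np.zeros_like(ppm)
    cos_p, sin_p = math.cos(phase0), math.sin(phase0)
    for x0, area in components:
        if area == 0.0:
            continue
        y += cos_p * lorentzian_absorption(ppm, x0, gamma, area)
        if sin_p != 0.0:
            y += sin_p * lorentzian_dispersion(ppm, x0, gamma, area)
    return y


def simulate_spectrum_pair(
    sample: SampleSpec,
    windows: list[MetaboliteWindow],
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int | None = None,
) -> tuple[Spectrum1D, Spectrum1D]:
    """Render the paired scans for one sample.

    Reference scan: every metabolite (and TMSP) at its window center with
    area proportional to its amount. Edited scan: areas scaled by the 13C
    enrichment fraction (TMSP by its steady-state factor). Phase error,
    polynomial baseline and independent Gaussian noise are applied to both.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    wm = window_map(windows)
    ppm = acq.ppm_axis()
    lo, hi = ppm[0], ppm[-1]

    missing = [m for m in sample.amounts if m not in wm]
    if TMSP not in wm:
        missing.append(TMSP)
    if missing:
        raise ValueError(f"no integration window for metabolite(s): {missing}")

    ref_comp: list[tuple[float, float]] = []
    edit_comp: list[tuple[float, float]] = []

    def add(center: float, total: float, labelled: float) -> None:
        if not lo <= center <= hi:
            raise ValueError(f"window center {center} ppm outside axis [{lo}, {hi}]")
        s = acq.satellite_split
        if s > 0:
            # 13C-bound protons split into a J-doublet; 12C-bound stay central
            ref_comp.append((center, total - labelled))
            for sign in (-1.0, 1.0):
                ref_comp.append((center + sign * s / 2, labelled / 2))
                edit_comp.append((center + sign * s / 2, labelled / 2))
        else:
            ref_comp.append((center, total))
            edit_comp.append((center, labelled))

    for m, amount in sample.amounts.items():
        add(wm[m].center, amount, amount * sample.enrichments[m])
    add(wm[TMSP].center, sample.tmsp_amount,
        sample.tmsp_amount * sample.tmsp_steady_factor)

    baseline = (np.polynomial.polynomial.polyval(ppm, list(acq.baseline_coeffs))
                if acq.baseline_coeffs else 0.0)
    rng = np.random.default_rng(seed)
    out = []
    for scan_type, comp in (("reference", ref_comp), ("edited", edit_comp)):
        y = _render(ppm, comp, acq.linewidth_gamma, acq.phase0) + baseline
        if acq.noise_sd > 0:
            y = y + rng.normal(0.0, acq.noise_sd, size=ppm.shape)
        out.append(Spectrum1D(ppm=ppm.copy(), intensity=y, scan_type=scan_type,
                              sample_id=sample.mouse_id and
                              f"{sample.mouse_id}_{sample.region}" or ""))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

class NonPSDCorrelationError(ValueError):
    pass


@dataclass
class CohortDesign:
    """Two-group, six-region cohort with known generating values."""

    n_per_group: int = 8
    regions: tuple = REGIONS
    metabolites: tuple = DEFAULT_METABOLITES
    baseline_amounts: dict = field(default_factory=lambda: dict(DEFAULT_AMOUNTS))
    baseline_enrichments: dict = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENTS))
    depletion_factors: dict = field(default_factory=lambda: dict(DEFAULT_DEPLETION))
    spared_set: tuple = DEFAULT_SPARED
    noise_cv: float = 0.1
    copula_corr: np.ndarray | None = None
    tmsp_amount: float = 1.0
    tmsp_steady_mean: float = DEFAULT_TMSP_STEADY_MEAN
    tmsp_steady_sd: float = DEFAULT_TMSP_STEADY_SD
    seed: int = 0
    repair_non_psd: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for m in self.metabolites:
            f = self.depletion_factors.get(m, 1.0)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"depletion factor for {m} outside (0, 1]: {f}")
        for m in self.spared_set:
            if self.depletion_factors.get(m, 1.0) != 1.0:
                raise ValueError(f"spared metabolite {m} must have factor 1.0")

    def corr_matrix(self) -> np.ndarray:
        m = len(self.metabolites)
        if self.copula_corr is None:
            return default_copula(self.metabolites, self.spared_set)
        c = np.asarray(self.copula_corr, dtype=float)
        if c.shape != (m, m):
            raise ValueError(f"copula_corr must be {m}x{m}")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("copula_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("copula_corr must have unit diagonal")
        evals, evecs = np.linalg.eigh(c)
        if evals.min() < -1e-10:
            if not self.repair_non_psd:
                raise NonPSDCorrelationError(
                    "copula_corr is not positive semi-definite "
                    f"(min eigenvalue {evals.min():.3g}); set repair_non_psd=True "
                    "to project onto the nearest PSD correlation matrix"
                )
            c = (evecs * np.clip(evals, 1e-10, None)) @ evecs.T
            d = np.sqrt(np.diag(c))
            c = c / np.outer(d, d)
        return c

    def with_correlation(self, pairs: dict) -> "CohortDesign":
        """New design with latent rank correlation set for named pairs."""
        idx = {name: i for i, name in enumerate(self.metabolites)}
        c = self.corr_matrix().copy()
        for (a, b), r in pairs.items():
            i, j = idx[a], idx[b]
            c[i, j] = c[j, i] = r
        return replace(self, copula_corr=c)


def simulate_cohort(design: CohortDesign) -> tuple[list[SampleSpec], pd.DataFrame]:
    """Draw a full cohort; returns the samples and the ground-truth table.

    Pure function of the design (including its seed): per sample, latent
    Gaussian-copula variates set the inter-metabolite rank structure, then
    a mean-preserving lognormal at ``noise_cv`` produces the enrichment
    around the group mean (control: baseline; ischemia: baseline x
    depletion factor). Amounts get independent lognormal scatter; the TMSP
    steady-state factor is drawn Normal(mean, sd).
    """
    mets = list(design.metabolites)
    corr = design.corr_matrix()
    # tiny jitter keeps Cholesky defined for exactly singular PSD matrices
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(mets)))
    sigma = math.sqrt(math.log(1.0 + design.noise_cv**2))
    rng = np.random.default_rng(design.seed)

    samples: list[SampleSpec] = []
    rows: list[dict] = []
    for group in GROUPS:
        for i in range(design.n_per_group):
            mouse_id = f"{'C' if group == 'control' else 'I'}{i + 1:02d}"
            for region in design.regions:
                z = chol @ rng.standard_normal(len(mets))
                w = rng.standard_normal(len(mets))
                tmsp_factor = rng.normal(design.tmsp_steady_mean,
                                         design.tmsp_steady_sd)
                enrichments, amounts = {}, {}
                for k, m in enumerate(mets):
                    mean_e = design.baseline_enrichments[m]
                    if group == "ischemia":
                        mean_e *= design.depletion_factors.get(m, 1.0)
                    # exp(sigma z - sigma^2/2) has mean 1 -> E[enr] = mean_e
                    e = mean_e * math.exp(sigma * z[k] - sigma**2 / 2.0)
                    enrichments[m] = min(max(e, 0.0), 1.0)
                    amounts[m] = design.baseline_amounts[m] * math.exp(
                        sigma * w[k] - sigma**2 / 2.0)
                samples.append(SampleSpec(
                    mouse_id=mouse_id, group=group, region=region,
                    amounts=amounts, enrichments=enrichments,
                    tmsp_amount=design.tmsp_amount,
                    tmsp_steady_factor=tmsp_factor,
                ))
                for m in mets:
                    rows.append({
                        "mouse_id": mouse_id, "group": group, "region": region,
                        "metabolite": m, "amount": amounts[m],
                        "enrichment": enrichments[m],
                        "enrichment_pct": 100.0 * enrichments[m],
                        "tmsp_steady_factor": tmsp_factor,
                    })
    return samples, pd.DataFrame(rows)


def render_cohort(
    samples: list[SampleSpec],
    windows: list[MetaboliteWindow],
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int = 0,
) -> list[tuple[Spectrum1D, Spectrum1D]]:
    """Render spectrum pairs for every sample, one child seed per sample."""
    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2**31 - 1, size=len(samples))
    return [simulate_spectrum_pair(s, windows, acq, seed=int(cs))
            for s, cs in zip(samples, child)]
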
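import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pocenmr.numutils import trapezoid_band
from pocenmr.quant import (
    enrichment_ratio,
    integrate_window,
    normalize_to_tmsp,
    out_of_range,
    quantify_cohort,
)
from pocenmr.spectrum import Spectrum1D
from pocenmr.synthdata import (
    DEFAULT_METABOLITES,
    CohortDesign,
    SampleSpec,
    lorentzian_absorption,
    render_cohort,
    simulate_cohort,
    simulate_spectrum_pair,
)
from pocenmr.windows import MetaboliteWindow


class TestIntegrateWindow:
    def test_ten_gamma_window_captures_arctan_fraction(self):
        """A unit-area Lorentzian integrated over +/- 10 gamma captures
        (2/pi) arctan(10) = 0.9365 of its area."""
        gamma = 0.005
        x = np.linspace(1.0, 3.0, 8192)
        s = Spectrum1D(x, lorentzian_absorption(x, 2.0, gamma))
        w = MetaboliteWindow("peak", 2.0, 2.0 - 10 * gamma, 2.0 + 10 * gamma)
        frac = 2.0 / math.pi * math.atan(10.0)
        assert integrate_window(s, w) == pytest.approx(frac, rel=5e-3)

    def test_zero_spectrum_integrates_to_zero(self):
        s = Spectrum1D(np.linspace(0, 5, 2048), np.zeros(2048))
        assert integrate_window(s, MetaboliteWindow("z", 2.0, 1.5, 2.5)) == 0.0

    def test_disjoint_halves_sum_to_full_window(self):
        x = np.linspace(1.0, 3.0, 4096)
        s = Spectrum1D(x, lorentzian_absorption(x, 2.0, 0.005))
        # split point off-grid on purpose
        full = integrate_window(s, MetaboliteWindow("f", 2.0, 1.9, 2.1))
        left = integrate_window(s, MetaboliteWindow("l", 1.95, 1.9, 2.00013))
        right = integrate_window(s, MetaboliteWindow("r", 2.05, 2.00013, 2.1))
        assert left + right == pytest.approx(full, abs=1e-9)

    def test_sign_preserved_for_negative_dips(self):
        x = np.linspace(0, 5, 2048)
        s = Spectrum1D(x, -np.ones(2048))
        assert integrate_window(s, MetaboliteWindow("n", 2.0, 1.0, 3.0)) == \
            pytest.approx(-2.0, rel=1e-6)

    def test_window_outside_spectrum_rejected(self):
        s = Spectrum1D(np.linspace(0, 1, 2048), np.zeros(2048))
        with pytest.raises(ValueError, match="far"):
            integrate_window(s, MetaboliteWindow("far", 3.0, 2.5, 3.5))


class TestEnrichmentRatio:
    @pytest.mark.parametrize("edit, ref, expected", [
        (30.0, 100.0, 30.0), (0.0, 5.0, 0.0), (1.1, 1.0, 110.0),
    ])
    def test_formula(self, edit, ref, expected):
        assert enrichment_ratio(edit, ref) == pytest.approx(expected)

    def test_nonpositive_reference_yields_missing_not_zero(self):
        assert math.isnan(enrichment_ratio(1.0, 0.0))
        assert math.isnan(enrichment_ratio(1.0, -2.0))

    def test_out_of_range_flagged_not_clipped(self):
        assert out_of_range(110.0) and out_of_range(-0.5)
        assert not out_of_range(50.0) and not out_of_range(float("nan"))

    def test_ratio_invariant_to_common_rescaling(self):
        base = enrichment_ratio(3.0, 10.0)
        for k in (0.1, 7.0, 1234.5):
            assert enrichment_ratio(3.0 * k, 10.0 * k) == pytest.approx(base)


class TestQuantifyCohort:
    @pytest.fixture(scope="class")
    def toy(self, windows, desk_acq):
        design = CohortDesign(n_per_group=2, regions=("FC",), noise_cv=0.0,
                              seed=5)
        samples, truth = simulate_cohort(design)
        pairs = render_cohort(samples, windows, desk_acq, seed=6)
        return samples, truth, pairs

    def test_cardinality_one_row_per_sample_and_window(self, toy, windows):
        samples, _, pairs = toy
        table = quantify_cohort(pairs, samples, windows)
        assert len(table) == len(samples) * len(windows)

    def test_rerun_is_deterministic(self, toy, windows):
        samples, _, pairs = toy
        t1 = quantify_cohort(pairs, samples, windows)
        t2 = quantify_cohort(pairs, samples, windows)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noise_free_uniform_enrichment_recovered(self, windows, desk_acq):
        """Every metabolite set to 50% enrichment comes back within 1 pp."""
        sample = SampleSpec("u", "control", "FC",
                            {m: 1.0 for m in DEFAULT_METABOLITES},
                            {m: 0.5 for m in DEFAULT_METABOLITES},
                            tmsp_steady_factor=1.0)
        ref, edi = simulate_spectrum_pair(sample, windows, desk_acq)
        table = quantify_cohort([(ref, edi)], [sample], windows)
        vals = table[table.metabolite != "TMSP"]["enrichment_pct"]
        assert np.all(np.abs(vals - 50.0) < 1.0)

    def test_noise_free_recovery_within_half_point(self, windows, desk_acq):
        """Default-design enrichments recovered within 0.5 pp for all 17
        metabolites on a noise-free sample."""
        design = CohortDesign(n_per_group=2, regions=("FC",), noise_cv=0.0,
                              seed=1)
        samples, truth = simulate_cohort(design)
        acq = dataclasses.replace(desk_acq, phase0=0.1,
                                  baseline_coeffs=(0.05, 0.02))
        pairs = render_cohort(samples[:1], windows, acq, seed=2)
        table = quantify_cohort(pairs, samples[:1], windows)
        merged = table.merge(truth, on=["mouse_id", "group", "region",
                                        "metabolite"])
        err = (merged["enrichment_pct_x"] - merged["enrichment_pct_y"]).abs()
        assert err.max() < 0.5

    def test_recovery_error_grows_with_noise(self, windows, desk_acq):
        """Mean |error| increases monotonically along a noise ladder
        (Spearman rank test across 10 seeds per level)."""
        sample = SampleSpec("n", "control", "FC", {"Lactate": 1.0},
                            {"Lactate": 0.4})
        ladder = [0.04, 0.16, 0.64, 2.56, 10.24]
        mean_err = []
        for sd in ladder:
            acq = dataclasses.replace(desk_acq, noise_sd=sd)
            errs = []
            for seed in range(10):
                ref, edi = simulate_spectrum_pair(sample, windows, acq,
                                                  seed=seed)
                t = quantify_cohort([(ref, edi)], [sample], windows,
                                    phi0=0.0)
                errs.append(abs(float(
                    t.loc[t.metabolite == "Lactate", "enrichment_pct"]) - 40.0))
            mean_err.append(np.mean(errs))
        rho = stats.spearmanr(ladder, mean_err).statistic
        assert rho == pytest.approx(1.0)

    def test_pairs_samples_mismatch_rejected(self, toy, windows):
        samples, _, pairs = toy
        with pytest.raises(ValueError, match="mismatch"):
            quantify_cohort(pairs[:1], samples, windows)


class TestNormalizeToTmsp:
    def _table(self, tmsp_refs, steady=1.1):
        rows = []
        for i, tr in enumerate(tmsp_refs):
            mid = f"C{i:02d}"
            rows.append({"mouse_id": mid, "group": "control", "region": "FC",
                         "metabolite": "TMSP", "ref_integral": tr,
                         "edit_integral": tr * steady,
                         "enrichment_pct": 100 * steady,
                         "out_of_range": True, "missing": False,
                         "normalized": False})
            rows.append({"mouse_id": mid, "group": "control", "region": "FC",
                         "metabolite": "Lactate", "ref_integral": tr * 0.9,
                         "edit_integral": tr * 0.9 * 0.4,
                         "enrichment_pct": 40.0, "out_of_range": False,
                         "missing": False, "normalized": False})
        return pd.DataFrame(rows)

    def test_equal_loading_is_noop(self):
        t = self._table([2.0, 2.0, 2.0])
        out, qc = normalize_to_tmsp(t)
        lac = out[out.metabolite == "Lactate"]
        np.testing.assert_allclose(lac["ref_integral"], 1.8)
        np.testing.assert_allclose(qc["loading_factor"], 1.0)

    def test_scaled_sample_normalised_and_ratio_invariant(self):
        t = self._table([1.0, 1.0, 2.0])
        out, qc = normalize_to_tmsp(t)
        f = qc.set_index("mouse_id")["loading_factor"]
        assert f["C02"] == pytest.approx(2.0 / np.mean([1.0, 1.0, 2.0]))
        lac = out[out.metabolite == "Lactate"].set_index("mouse_id")
        # enrichment (a ratio) is unchanged by the loading correction
        np.testing.assert_allclose(lac["enrichment_pct"], 40.0, atol=1e-9)
        np.testing.assert_allclose(
            lac.loc["C02", "ref_integral"], lac.loc["C00", "ref_integral"],
            atol=1e-9)

    def test_missing_tmsp_record_rejected(self):
        t = self._table([1.0, 1.0])
        t = t[~((t.mouse_id == "C01") & (t.metabolite == "TMSP"))]
        with pytest.raises(ValueError, match="TMSP"):
            normalize_to_tmsp(t)

    def test_qc_mean_recovers_generator_steady_state(self, windows, desk_acq):
        """48-sample cohort: QC steady-ratio mean lands within 0.03 of the
        generating 1.10 mean."""
        design = CohortDesign(n_per_group=4, seed=9)
        samples, _ = simulate_cohort(design)
        acq = dataclasses.replace(desk_acq, noise_sd=0.3)
        pairs = render_cohort(samples, windows, acq, seed=10)
        table = quantify_cohort(pairs, samples, windows, phi0=0.0)
        _, qc = normalize_to_tmsp(table)
        assert qc["steady_ratio"].mean() == pytest.approx(1.10, abs=0.03)
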
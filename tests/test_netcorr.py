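import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pocenmr.netcorr import (
    edges_to_matrix,
    hub_scores,
    metabolite_network,
    regional_network,
    spearman_test,
    to_graphml,
)
from pocenmr.synthdata import REGIONS, CohortDesign, simulate_cohort


def _table_from_matrix(values: np.ndarray, metabolites, group="control"):
    """Long enrichment table from an (observations x metabolites) array."""
    rows = []
    n_regions = len(REGIONS)
    for i in range(values.shape[0]):
        mouse, region = f"C{i // n_regions:02d}", REGIONS[i % n_regions]
        for j, m in enumerate(metabolites):
            rows.append({"mouse_id": mouse, "group": group, "region": region,
                         "metabolite": m, "enrichment_pct": values[i, j]})
    return pd.DataFrame(rows)


class TestSpearmanTest:
    def test_monotone_function_of_x_has_rho_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8])
        rho, p, n = spearman_test(x, np.exp(x))
        assert rho == 1.0 and n == 8
        assert p <= 1e-4  # extreme tail of the exact n=8 null

    def test_exact_small_n_p_matches_brute_force(self):
        """Exact permutation p for n=6 agrees with direct enumeration."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p, _ = spearman_test(x, y)
        rhos = []
        for perm in itertools.permutations(range(6)):
            d2 = sum((perm[i] - i) ** 2 for i in range(6))
            rhos.append(1 - 6 * d2 / (6 * 35))
        brute = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(brute, abs=1e-12)

    def test_constant_series_is_undefined(self):
        rho, p, n = spearman_test(np.ones(8), np.arange(8.0))
        assert np.isnan(rho) and np.isnan(p)

    @given(st.integers(0, 2**31 - 1))
    def test_rho_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho0, _, _ = spearman_test(x, y)
        rho1, _, _ = spearman_test(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho0, abs=1e-12)


class TestMetaboliteNetwork:
    def test_null_networks_rarely_retain_edges(self):
        """Independent metabolites (identity copula): mean retained-edge
        count stays below 0.05 per network across 200 seeds."""
        total = 0
        for seed in range(200):
            _, truth = simulate_cohort(
                CohortDesign(seed=seed, copula_corr=np.eye(17)))
            edges = metabolite_network(truth, "control")
            total += int(edges["retained"].sum())
        assert total / 200 <= 0.05

    def test_planted_lactate_alanine_edge_recovered(self):
        """Latent rho 0.92: Lac-Ala edge retained (rho > 0.8, q < 0.01) in
        at least 90 of 100 seeds."""
        hits = 0
        for seed in range(100):
            d = CohortDesign(seed=seed, copula_corr=np.eye(17)).with_correlation(
                {("Lactate", "Ala"): 0.92})
            _, truth = simulate_cohort(d)
            edges = metabolite_network(truth, "control")
            pair = edges[(edges.item_a == "Ala") & (edges.item_b == "Lactate")
                         | (edges.item_a == "Lactate") & (edges.item_b == "Ala")]
            hits += bool(pair.iloc[0]["retained"])
        assert hits >= 90

    def test_bh_q_dominates_p_and_is_monotone(self):
        d = CohortDesign(seed=42).with_correlation({("Lactate", "Ala"): 0.9,
                                                    ("Glu3", "Glu4"): 0.7})
        _, truth = simulate_cohort(d)
        edges = metabolite_network(truth, "control").dropna(subset=["p_raw"])
        assert (edges["q_fdr"] >= edges["p_raw"] - 1e-12).all()
        assert edges["q_fdr"].between(0, 1).all()
        srt = edges.sort_values("p_raw")
        assert (np.diff(srt["q_fdr"]) >= -1e-12).all()

    def test_tmsp_excluded_and_pair_count(self):
        _, truth = simulate_cohort(CohortDesign(seed=0))
        edges = metabolite_network(truth, "control")
        mets = set(edges.item_a) | set(edges.item_b)
        assert "TMSP" not in mets
        assert len(edges) == 17 * 16 // 2  # 136 pairs among 17 metabolites

    def test_graphml_export_roundtrip(self, tmp_path):
        import networkx as nx
        d = CohortDesign(seed=3).with_correlation({("Lactate", "Ala"): 0.95})
        _, truth = simulate_cohort(d)
        edges = metabolite_network(truth, "control")
        path = tmp_path / "net.graphml"
        to_graphml(edges, path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 17
        assert g.number_of_edges() == int(edges["retained"].sum())


def _regional_table(rng, coupled=(), rho=0.9, n_mice=8, metabolite="Lactate"):
    """Mouse x region table with a shared latent factor in coupled regions."""
    rows = []
    for i in range(n_mice):
        latent = rng.normal()
        for region in REGIONS:
            z = rng.normal()
            if region in coupled:
                val = np.sqrt(rho) * latent + np.sqrt(1 - rho) * z
            else:
                val = z
            rows.append({"mouse_id": f"C{i:02d}", "group": "control",
                         "region": region, "metabolite": metabolite,
                         "enrichment_pct": 20.0 + 5.0 * val})
    return pd.DataFrame(rows)


class TestRegionalNetwork:
    def test_identical_regions_fully_correlated(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        rows = [{"mouse_id": f"C{i:02d}", "group": "control", "region": r,
                 "metabolite": "Lactate", "enrichment_pct": 20 + base[i]}
                for i in range(8) for r in REGIONS]
        edges = regional_network(pd.DataFrame(rows), "Lactate", "control")
        assert (edges["rho"] == 1.0).all()
        assert len(edges) == 15

    def test_independent_regions_retain_nothing(self):
        kept = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            edges = regional_network(_regional_table(rng), "Lactate", "control")
            kept += int(edges["retained"].sum())
        assert kept / (200 * 15) <= 0.01

    def test_planted_regional_coupling_dominates_retained_set(self):
        """Cortex-striatum-thalamus coupling: those three pairs are retained
        far more often than any uncoupled pair across 100 seeds."""
        coupled = ("FC", "STR", "THA")
        coupled_pairs = {tuple(sorted(p))
                         for p in itertools.combinations(coupled, 2)}
        counts: dict = {}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            edges = regional_network(
                _regional_table(rng, coupled=coupled, rho=0.9),
                "Lactate", "control")
            for _, r in edges[edges["retained"]].iterrows():
                counts[tuple(sorted((r.item_a, r.item_b)))] = \
                    counts.get(tuple(sorted((r.item_a, r.item_b))), 0) + 1
        top3 = sorted(counts, key=counts.get, reverse=True)[:3]
        assert set(top3) == coupled_pairs
        uncoupled_hits = sum(v for k, v in counts.items()
                             if k not in coupled_pairs)
        assert uncoupled_hits <= 0.01 * 100 * 12  # 12 uncoupled pairs

    def test_matrix_view_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        edges = regional_network(_regional_table(rng), "Lactate", "control")
        m = edges_to_matrix(edges, "rho")
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.values), 1.0)


class TestHubScores:
    def test_fully_connected_triangle_closed_form(self):
        edges = pd.DataFrame({
            "item_a": ["A", "A", "B"], "item_b": ["B", "C", "C"],
            "rho": [0.9, -0.9, 0.9], "n_obs": [10] * 3,
            "p_raw": [1e-6] * 3, "q_fdr": [1e-6] * 3,
            "retained": [True] * 3,
        })
        hubs = hub_scores(edges).set_index("node")
        assert (hubs["degree"] == 2).all()
        np.testing.assert_allclose(hubs["strength"], 1.8)

    def test_empty_network_scores_zero_with_warning(self):
        edges = pd.DataFrame({
            "item_a": ["A"], "item_b": ["B"], "rho": [0.1], "n_obs": [10],
            "p_raw": [0.9], "q_fdr": [0.9], "retained": [False],
        })
        with pytest.warns(UserWarning, match="no retained"):
            hubs = hub_scores(edges)
        assert (hubs["degree"] == 0).all() and (hubs["strength"] == 0).all()

    def test_planted_thalamic_hub_tops_strength_ranking(self):
        """One-factor design with the thalamus as the factor: THA couples
        0.8 to every other region while they couple only 0.64 among
        themselves, so THA must rank first by strength in at least 95 of
        100 seeds (24 mice and lenient retention keep the strength
        estimates stable; empty networks would tie all nodes at zero)."""
        lam = 0.8
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(24):
                hub = rng.normal()
                for r in REGIONS:
                    v = hub if r == "THA" else \
                        lam * hub + np.sqrt(1 - lam**2) * rng.normal()
                    rows.append({"mouse_id": f"C{i:02d}", "group": "control",
                                 "region": r, "metabolite": "Lactate",
                                 "enrichment_pct": 20 + 5 * v})
            edges = regional_network(pd.DataFrame(rows), "Lactate", "control",
                                     rho_min=0.3, q_max=0.05)
            hubs = hub_scores(edges)
            wins += hubs.iloc[0]["node"] == "THA"
        assert wins >= 95
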
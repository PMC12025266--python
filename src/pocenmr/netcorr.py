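"""Spearman correlation networks over enrichment tables, with FDR control.

Two views of metabolic coordination:

* *metabolite networks* — for one experimental group, correlate every
  unordered metabolite pair across the (mouse x region) observations;
* *regional matrices* — for one metabolite, correlate every region pair
  across mice.

Edges are retained when BOTH |rho| > 0.8 and the Benjamini-Hochberg
adjusted q < 0.01 (strict inequalities). p-values use the exact
permutation distribution of Spearman's rho for n <= 9 untied samples and
the t approximation otherwise. Hub scoring summarises each node's
retained-edge degree and summed |rho| strength.
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import TMSP

RHO_MIN = 0.8
Q_MAX = 0.01
EXACT_N_MAX = 9

EDGE_COLUMNS = ["item_a", "item_b", "rho", "n_obs", "p_raw", "q_fdr", "retained"]


@lru_cache(maxsize=16)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    d2 = ((base[perms] - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1.0))
    return np.sort(np.abs(rho))


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho and two-sided p; returns (rho, p, n).

    Exact permutation p for n <= 9 with no ties; otherwise the usual
    t-distribution approximation. Constant input yields (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        return math_nan, math_nan, n
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math_nan, math_nan, n
    rho = float(stats.spearmanr(x, y).statistic)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_N_MAX and not ties:
        null = _exact_null_abs_rho(n)
        # P(|rho_null| >= |rho|) via right tail on the sorted null
        k = np.searchsorted(null, abs(rho) - 1e-12, side="left")
        p = (len(null) - k) / len(null)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(p), n


math_nan = float("nan")


def _bh_retain(df: pd.DataFrame, rho_min: float, q_max: float) -> pd.DataFrame:
    """BH-adjust the testable rows jointly and apply the retention rule."""
    df = df.copy()
    df["q_fdr"] = np.nan
    testable = df["p_raw"].notna()
    if testable.any():
        df.loc[testable, "q_fdr"] = multipletests(
            df.loc[testable, "p_raw"].to_numpy(), method="fdr_bh")[1]
    df["retained"] = (
        testable
        & (df["rho"].abs() > rho_min)
        & (df["q_fdr"] < q_max)
    )
    return df


def metabolite_network(
    table: pd.DataFrame,
    group: str,
    rho_min: float = RHO_MIN,
    q_max: float = Q_MAX,
    method: str = "spearman",
    value_col: str = "enrichment_pct",
    pool_mice: bool = False,
) -> pd.DataFrame:
    """Pairwise metabolite correlation edges within one group.

    The observation unit is the (mouse, region) record — up to 48 per
    group in the default design. ``pool_mice=True`` instead averages the
    six regions per mouse first (the coarser reading of "within identical
    samples"). ``method='pearson'`` is available for comparison with
    normality-assuming analyses.
    """
    sub = table[(table["group"] == group) & (table["metabolite"] != TMSP)]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    wide = sub.pivot_table(index=["mouse_id", "region"], columns="metabolite",
                           values=value_col, aggfunc="mean")
    if pool_mice:
        wide = wide.groupby(level="mouse_id").mean()

    rows = []
    mets = list(wide.columns)
    for a, b in itertools.combinations(mets, 2):
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if method == "pearson":
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 4 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                rho, p = math_nan, math_nan
            else:
                r = stats.pearsonr(x[ok], y[ok])
                rho, p = float(r.statistic), float(r.pvalue)
        elif method == "spearman":
            rho, p, n = spearman_test(x, y)
        else:
            raise ValueError("method must be 'spearman' or 'pearson'")
        if np.isnan(rho):
            warnings.warn(f"constant or short series for pair ({a}, {b}); "
                          "correlation undefined", stacklevel=2)
        rows.append({"item_a": a, "item_b": b, "rho": rho, "n_obs": n,
                     "p_raw": p})
    return _bh_retain(pd.DataFrame(rows), rho_min, q_max)[EDGE_COLUMNS]


def regional_network(
    table: pd.DataFrame,
    metabolite: str,
    group: str,
    rho_min: float = RHO_MIN,
    q_max: float = Q_MAX,
) -> pd.DataFrame:
    """Region-pair correlation of one metabolite's enrichment across mice.

    BH correction runs over the region pairs (15 for six regions).
    Unbalanced regions fall back to pairwise-complete observations with a
    warning. Returns an edge list; see :func:`edges_to_matrix` for the
    square rho/q matrices.
    """
    sub = table[(table["group"] == group) & (table["metabolite"] == metabolite)]
    if sub.empty:
        raise ValueError(f"no records for {metabolite!r} in group {group!r}")
    wide = sub.pivot_table(index="mouse_id", columns="region",
                           values="enrichment_pct", aggfunc="mean")
    if wide.isna().any().any():
        warnings.warn("unbalanced regions: using pairwise-complete mice",
                      stacklevel=2)
    if len(wide) < 4:
        raise ValueError("need at least 4 mice per region")
    rows = []
    for a, b in itertools.combinations(list(wide.columns), 2):
        rho, p, n = spearman_test(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append({"item_a": a, "item_b": b, "rho": rho, "n_obs": n,
                     "p_raw": p})
    return _bh_retain(pd.DataFrame(rows), rho_min, q_max)[EDGE_COLUMNS]


def edges_to_matrix(edges: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Symmetric matrix view of an edge list (diagonal rho = 1, q = 0)."""
    nodes = sorted(set(edges["item_a"]) | set(edges["item_b"]))
    m = pd.DataFrame(np.nan, index=nodes, columns=nodes)
    for _, r in edges.iterrows():
        m.loc[r["item_a"], r["item_b"]] = r[value]
        m.loc[r["item_b"], r["item_a"]] = r[value]
    np.fill_diagonal(m.values, 1.0 if value == "rho" else 0.0)
    return m


def hub_scores(edges: pd.DataFrame) -> pd.DataFrame:
    """Retained-edge degree and strength (sum |rho|) per node, ranked.

    An empty (no retained edges) network yields all-zero scores with a
    warning rather than an error.
    """
    nodes = sorted(set(edges["item_a"]) | set(edges["item_b"]))
    degree = {n: 0 for n in nodes}
    strength = {n: 0.0 for n in nodes}
    kept = edges[edges["retained"]]
    if kept.empty:
        warnings.warn("no retained edges; hub scores are all zero", stacklevel=2)
    for _, r in kept.iterrows():
        for n in (r["item_a"], r["item_b"]):
            degree[n] += 1
            strength[n] += abs(r["rho"])
    out = pd.DataFrame({
        "node": nodes,
        "degree": [degree[n] for n in nodes],
        "strength": [strength[n] for n in nodes],
    }).sort_values(["strength", "degree", "node"],
                   ascending=[False, False, True], ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def to_graphml(edges: pd.DataFrame, path, retained_only: bool = True) -> None:
    """Write the network as GraphML (edge attributes rho, p, q)."""
    import networkx as nx

    g = nx.Graph()
    sub = edges[edges["retained"]] if retained_only else edges
    g.add_nodes_from(sorted(set(edges["item_a"]) | set(edges["item_b"])))
    for _, r in sub.iterrows():
        if np.isnan(r["rho"]):
            continue
        g.add_edge(r["item_a"], r["item_b"], rho=float(r["rho"]),
                   p_raw=float(r["p_raw"]), q_fdr=float(r["q_fdr"]),
                   retained=bool(r["retained"]))
    nx.write_graphml(g, path)
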
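"""Genus-pollutant correlation tables and signed bipartite networks.

Each dominant genus's relative abundance is correlated against each
pollutant variable (removal rate or concentration) across shared samples,
Spearman by default.  Pairs passing an |rho| and p threshold become signed
edges of a bipartite network whose node sizes carry mean abundance or
concentration; the network is written as GraphML plus an edge-list TSV.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman", "correlation_table", "build_network"]

#: sample-size cutoff below which the Spearman p-value is exact
EXACT_N = 7


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks.

    The two-sided p-value is exact (enumeration of all rank permutations)
    for n <= 7 and the t-approximation otherwise.  Constant input is an
    error (rank correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_N:
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    # t approximation, as scipy uses for moderate n
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def correlation_table(
    abundance: pd.DataFrame,
    variables: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """All taxon x variable correlations over shared samples.

    ``abundance`` is taxa x samples (relative abundances); ``variables``
    is samples x variables (e.g. final removal rates per system).  Returns
    a tidy frame (taxon, variable, rho, p, q, significant) with BH
    adjustment across the whole grid; the significance flag follows raw
    p < 0.05.
    """
    shared = [s for s in abundance.columns if s in variables.index]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared samples, found {len(shared)}"
        )
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for taxon in abundance.index:
        a = abundance.loc[taxon, shared].to_numpy(dtype=float)
        for var in variables.columns:
            v = variables.loc[shared, var].to_numpy(dtype=float)
            if method == "spearman":
                rho, p = spearman(a, v)
            else:
                rho, p = stats.pearsonr(a, v)
            rows.append(
                {"taxon": taxon, "variable": var, "rho": float(rho),
                 "p": float(p)}
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < 0.05
    return out


def build_network(
    corr: pd.DataFrame,
    node_sizes: dict | None = None,
    rho_min: float = 0.6,
    alpha: float = 0.05,
) -> nx.Graph:
    """Signed bipartite taxon-variable network from a correlation table.

    Edges connect pairs with |rho| >= ``rho_min`` and p < ``alpha``; edge
    attributes carry rho, sign and weight = |rho|.  Node attribute ``kind``
    distinguishes taxa from pollutant variables and ``size`` carries the
    mean relative abundance or concentration when provided.
    """
    node_sizes = node_sizes or {}
    g = nx.Graph()
    for taxon in pd.unique(corr["taxon"]):
        g.add_node(taxon, kind="taxon", size=float(node_sizes.get(taxon, 1.0)))
    for var in pd.unique(corr["variable"]):
        g.add_node(var, kind="pollutant", size=float(node_sizes.get(var, 1.0)))
    passing = corr[(corr["rho"].abs() >= rho_min) & (corr["p"] < alpha)]
    for _, row in passing.iterrows():
        if row["taxon"] == row["variable"]:
            continue
        g.add_edge(
            row["taxon"], row["variable"],
            rho=float(row["rho"]),
            sign="+" if row["rho"] >= 0 else "-",
            weight=float(abs(row["rho"])),
        )
    return g
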
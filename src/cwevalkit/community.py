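"""Beta diversity and differential-abundance analysis of count tables.

Bray-Curtis dissimilarities between samples feed a UPGMA (size-weighted
average linkage) clustering whose dendrogram is ultrametric and can be
written as Newick.  Group differences are screened per taxon with
Kruskal-Wallis (exact by permutation at small n) and ranked with a
LEfSe-style linear-discriminant effect size; phylum-level shifts are
summarised as percentage-point differences with BH-adjusted rank-sum tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, aggregate_lineage, relative_abundance

__all__ = [
    "DistanceMatrix",
    "UltrametricTree",
    "bray_curtis",
    "upgma",
    "dominant_taxa",
    "kruskal_wallis",
    "lefse_like",
    "abundance_shift",
]


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis(rel: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns of a relative table.

    d(u, v) = 1 - 2 sum min(u_i, v_i) / (sum u + sum v); with columns
    normalised to 1 this is also sum |u - v| / 2.
    """
    sums = rel.sum(axis=0)
    off = sums.index[(sums - 1.0).abs() > 1e-6]
    if len(off):
        raise ValueError(
            f"columns not normalised to 1: {list(off)}; pass relative abundances"
        )
    X = rel.to_numpy(dtype=float).T  # samples x taxa
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = X[i].sum() + X[j].sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * np.minimum(X[i], X[j]).sum() / denom
    return DistanceMatrix(list(rel.columns), d)


@dataclass
class _Node:
    height: float
    label: str | None = None
    children: list = field(default_factory=list)  # (node, branch_length)

    def leaves(self) -> list:
        if self.label is not None:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, top: bool = True) -> str:
        if self.label is not None:
            s = self.label
        else:
            s = "(" + ",".join(
                f"{child.newick(top=False)}:{blen:.10g}"
                for child, blen in self.children
            ) + ")"
        return s + ";" if top else s


@dataclass
class UltrametricTree:
    """UPGMA dendrogram: merge list plus a Newick rendering.

    ``merges`` records, in order, ``(members_a, members_b, height)`` with
    members as sorted leaf tuples; heights are half the inter-cluster
    distance and non-decreasing.
    """

    leaves: list
    merges: list
    root: _Node

    def to_newick(self) -> str:
        return self.root.newick()

    def leaf_root_distances(self) -> dict:
        out = {}

        def walk(node: _Node, depth: float):
            if node.label is not None:
                out[node.label] = depth
            for child, blen in node.children:
                walk(child, depth + blen)

        walk(self.root, 0.0)
        return out

    def cophenetic(self) -> pd.DataFrame:
        """Leaf-pair distances implied by the dendrogram (2 x merge height)."""
        n = len(self.leaves)
        df = pd.DataFrame(0.0, index=self.leaves, columns=self.leaves)

        def walk(node: _Node):
            if node.label is not None:
                return
            kids = [child for child, _ in node.children]
            for a, b in itertools.combinations(kids, 2):
                for la in a.leaves():
                    for lb in b.leaves():
                        df.loc[la, lb] = df.loc[lb, la] = 2.0 * node.height
            for child in kids:
                walk(child)

        walk(self.root)
        return df


def upgma(dm: DistanceMatrix) -> UltrametricTree:
    """UPGMA clustering: merge closest pair, heights = distance / 2.

    Distances to a merged cluster are size-weighted means of the member
    distances.  Distance ties are broken by the lexicographically smallest
    (members_a, members_b) pair of sorted leaf tuples.
    """
    if len(dm.labels) < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    clusters: dict[tuple, _Node] = {
        (lab,): _Node(height=0.0, label=lab) for lab in dm.labels
    }
    dist: dict[frozenset, float] = {}
    labs = list(dm.labels)
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            dist[frozenset(((labs[i],), (labs[j],)))] = dm.values[i, j]

    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = dist[frozenset((a, b))]
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        height = d / 2.0
        node_a, node_b = clusters.pop(a), clusters.pop(b)
        merged = tuple(sorted(a + b))
        node = _Node(
            height=height,
            children=[
                (node_a, height - node_a.height),
                (node_b, height - node_b.height),
            ],
        )
        merges.append((a, b, height))
        for other in clusters:
            na, nb = len(a), len(b)
            d_new = (
                na * dist.pop(frozenset((a, other)))
                + nb * dist.pop(frozenset((b, other)))
            ) / (na + nb)
            dist[frozenset((merged, other))] = d_new
        dist.pop(frozenset((a, b)), None)
        clusters[merged] = node

    root = next(iter(clusters.values()))
    return UltrametricTree(leaves=list(dm.labels), merges=merges, root=root)


def dominant_taxa(rel: pd.DataFrame, threshold: float = 0.001) -> pd.DataFrame:
    """Keep taxa exceeding ``threshold`` relative abundance in any sample.

    The remainder is pooled into an ``other`` row so columns still sum to 1.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    keep = (rel > threshold).any(axis=1)
    kept = rel.loc[keep]
    rest = rel.loc[~keep]
    if len(rest):
        other = rest.sum(axis=0).to_frame("other").T
        kept = pd.concat([kept, other])
    return kept


def _kw_statistic(ranks: np.ndarray, sizes: list, tie_term: float) -> float:
    N = len(ranks)
    start = 0
    s = 0.0
    for n in sizes:
        rsum = ranks[start:start + n].sum()
        s += rsum * rsum / n
        start += n
    h = 12.0 / (N * (N + 1)) * s - 3.0 * (N + 1)
    return h / tie_term if tie_term > 0 else 0.0


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with midranks and tie correction.

    The p-value is exact (complete enumeration of group assignments) when
    the pooled sample size is <= 8, and the chi-square approximation with
    df = n_groups - 1 otherwise.  Identical values across all groups give
    (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    sizes = [len(g) for g in groups]
    h = _kw_statistic(ranks, sizes, tie_term)

    if N <= 8:
        count = 0
        total = 0
        indices = list(range(N))

        def assignments(remaining, sizes_left):
            if not sizes_left:
                yield []
                return
            n = sizes_left[0]
            for combo in itertools.combinations(remaining, n):
                rest = [i for i in remaining if i not in combo]
                for tail in assignments(rest, sizes_left[1:]):
                    yield [combo] + tail

        for assign in assignments(indices, sizes):
            perm_ranks = np.concatenate([ranks[list(c)] for c in assign])
            h_perm = _kw_statistic(perm_ranks, sizes, tie_term)
            count += h_perm >= h - 1e-12
            total += 1
        return float(h), count / total
    df = len(groups) - 1
    return float(h), float(stats.chi2.sf(h, df))


def _lda_direction(X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Ridge-regularised Fisher discriminant axis for two classes."""
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = np.cov(X0, rowvar=False, ddof=1) + np.cov(X1, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    p = S.shape[0]
    ridge = 1e-6 * (np.trace(S) / p + 1.0)
    w = np.linalg.solve(S + ridge * np.eye(p), mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0:
        diff = mu1 - mu0
        norm_d = np.linalg.norm(diff)
        return diff / norm_d if norm_d > 0 else np.zeros(p)
    return w / norm


def lefse_like(
    table: CountTable,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    boot: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """LEfSe-style differential features: KW screen + LDA effect size.

    Relative abundances are scaled to 1e6 per sample.  Features passing a
    Kruskal-Wallis screen across groups at ``alpha`` get an effect size
    from ``boot`` bootstrap resamples: per resample a two-class linear
    discriminant (feature's top-mean group vs the rest) is fitted on the
    surviving features and effect(f) = |w_f * s + delta_f| / 2, where w is
    the unit discriminant axis, s the projected class-mean separation and
    delta_f the raw class-mean difference.  The reported score is
    log10(max(mean effect, 1)); features with score >= ``lda_threshold``
    are returned, assigned to their highest-mean group.
    """
    groups = sorted(set(table.groups.values()))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    group_samples = {g: table.samples_in_group(g) for g in groups}
    if any(len(s) < 2 for s in group_samples.values()):
        raise ValueError("every group needs >= 2 replicate samples")

    scaled = relative_abundance(table) * 1e6
    rng = np.random.default_rng(seed)

    survivors = []
    kw_p = {}
    for taxon in scaled.index:
        vals = [scaled.loc[taxon, group_samples[g]].to_numpy() for g in groups]
        _, p = kruskal_wallis(vals)
        if p <= alpha:
            survivors.append(taxon)
            kw_p[taxon] = p
    if not survivors:
        return pd.DataFrame(
            columns=["taxon", "enriched_group", "kw_p", "lda_score"]
        )

    sub = scaled.loc[survivors]
    group_means = pd.DataFrame(
        {g: sub[group_samples[g]].mean(axis=1) for g in groups}
    )
    top_group = group_means.idxmax(axis=1)

    records = []
    for taxon in survivors:
        g1 = top_group[taxon]
        s1 = group_samples[g1]
        s0 = [s for g in groups if g != g1 for s in group_samples[g]]
        X1_full = sub[s1].to_numpy().T  # samples x features
        X0_full = sub[s0].to_numpy().T
        f = survivors.index(taxon)
        effects = []
        for _ in range(boot):
            i1 = rng.integers(0, len(s1), size=len(s1))
            i0 = rng.integers(0, len(s0), size=len(s0))
            X1, X0 = X1_full[i1], X0_full[i0]
            w = _lda_direction(X0, X1)
            mu_diff = X1.mean(axis=0) - X0.mean(axis=0)
            s_proj = float(w @ mu_diff)
            effects.append(abs(w[f] * s_proj + mu_diff[f]) / 2.0)
        score = math.log10(max(float(np.mean(effects)), 1.0))
        if score >= lda_threshold:
            records.append(
                {
                    "taxon": taxon,
                    "enriched_group": g1,
                    "kw_p": kw_p[taxon],
                    "lda_score": score,
                }
            )
    return pd.DataFrame(records, columns=["taxon", "enriched_group", "kw_p", "lda_score"])


def abundance_shift(
    table: CountTable, group_a: str, group_b: str, rank: str = "phylum"
) -> pd.DataFrame:
    """Per-taxon change in mean relative abundance between two groups.

    Differences are in percentage points (group_a minus group_b) at the
    requested lineage rank, with two-sided rank-sum p-values and BH-FDR
    q-values across taxa.  The deltas sum to zero (compositional identity).
    """
    agg = aggregate_lineage(table, rank)
    rel = relative_abundance(agg) * 100.0
    sa = agg.samples_in_group(group_a)
    sb = agg.samples_in_group(group_b)
    if not sa or not sb:
        raise ValueError(f"group(s) not present: {group_a!r}, {group_b!r}")
    rows = []
    for taxon in rel.index:
        va, vb = rel.loc[taxon, sa].to_numpy(), rel.loc[taxon, sb].to_numpy()
        if np.ptp(np.concatenate([va, vb])) == 0:
            p = 1.0
        else:
            _, p = stats.ranksums(va, vb)
        rows.append(
            {"taxon": taxon, "delta_pct": va.mean() - vb.mean(), "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < 0.05
    return out
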
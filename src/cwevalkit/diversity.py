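"""Alpha-diversity indices for taxon count tables.

Richness is summarised by the observed taxon count and the Chao1 estimator,
evenness by Shannon entropy (natural log) and the Gini-Simpson index
(1 - sum p^2), and sampling completeness by Good's coverage.  Indices are
computed on raw counts, without rarefaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._cld import tukey_letters
from .tables import CountTable

__all__ = [
    "observed_otus",
    "chao1",
    "shannon",
    "simpson",
    "goods_coverage",
    "alpha_table",
]


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return c


def observed_otus(counts) -> int:
    """Number of taxa with count > 0."""
    return int((_as_counts(counts) > 0).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton and doubleton counts.

    S_obs + F1^2 / (2 F2) when doubletons exist; the bias-corrected
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0.  Requires integer
    counts (the estimator is undefined for non-integers).
    """
    c = _as_counts(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError("Chao1 requires integer counts")
    s_obs = (c > 0).sum()
    f1 = (c == 1).sum()
    f2 = (c == 2).sum()
    if f2 > 0:
        return float(s_obs + f1 ** 2 / (2 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2)


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p (natural log unless ``base`` given)."""
    c = _as_counts(counts)
    total = c.sum()
    if total == 0:
        raise ValueError("empty sample: Shannon undefined")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum p^2 (probability of interspecific draw)."""
    c = _as_counts(counts)
    total = c.sum()
    if total == 0:
        raise ValueError("empty sample: Simpson undefined")
    p = c / total
    return float(1.0 - (p ** 2).sum())


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: estimated fraction of the community sampled."""
    c = _as_counts(counts)
    total = c.sum()
    if total == 0:
        raise ValueError("empty sample: coverage undefined")
    f1 = (c == 1).sum()
    return float(1.0 - f1 / total)


_INDICES = {
    "otus": observed_otus,
    "chao1": chao1,
    "shannon": shannon,
    "simpson": simpson,
    "coverage": goods_coverage,
}

_LETTERED = ("chao1", "shannon", "simpson")


def alpha_table(
    table: CountTable, alpha: float = 0.05, shannon_base: float | None = None
) -> pd.DataFrame:
    """Per-sample alpha-diversity table with group means and Tukey letters.

    Returns one row per sample (columns: sample, group, otus, chao1,
    shannon, simpson, coverage) followed by one ``<group> (mean)`` row per
    group.  When every group has >= 2 replicate samples, compact letters
    from one-way ANOVA + Tukey HSD at ``alpha`` are attached to the mean
    rows for Chao1, Shannon and Simpson; with single replicates the letter
    columns are omitted.
    """
    rows = []
    for sample in table.samples:
        c = table.counts[sample].to_numpy()
        row = {"sample": sample, "group": table.group_of(sample)}
        for name, fn in _INDICES.items():
            row[name] = fn(c) if name != "shannon" else shannon(c, shannon_base)
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    group_sizes = per_sample.groupby("group").size()
    means = per_sample.groupby("group", sort=False)[list(_INDICES)].mean()
    mean_rows = means.reset_index()
    mean_rows.insert(0, "sample", mean_rows["group"] + " (mean)")

    with_letters = (group_sizes >= 2).all() and len(group_sizes) >= 2
    if with_letters:
        for index in _LETTERED:
            letters = tukey_letters(
                per_sample[index].to_numpy(), per_sample["group"].to_numpy(),
                alpha=alpha,
            )
            mean_rows[f"{index}_letter"] = mean_rows["group"].map(letters)
    out = pd.concat([per_sample, mean_rows], ignore_index=True)
    return out
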
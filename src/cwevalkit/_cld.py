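"""One-way ANOVA + Tukey HSD compact letter display (insert-absorb)."""

from __future__ import annotations

import string

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def tukey_letters(values, groups, alpha: float = 0.05) -> dict:
    """Assign compact letters so groups sharing a letter do not differ.

    ``values``/``groups`` are parallel sequences with >= 2 replicates per
    group.  Pairs not rejected by Tukey HSD at ``alpha`` share a letter;
    letters are assigned over groups sorted by descending mean (the
    convention of treatment-comparison figures).  Returns
    ``{group: letters}``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups), key=lambda g: -values[groups == g].mean())
    if len(labels) == 1:
        return {labels[0]: "a"}
    counts = {g: int((groups == g).sum()) for g in labels}
    if min(counts.values()) < 2:
        raise ValueError("letter display requires >= 2 replicates per group")

    if all(np.ptp(values[groups == g]) == 0 for g in labels):
        # degenerate ANOVA (zero within-group variance): identical values
        # share a letter, distinct values get distinct letters
        if np.ptp(values) == 0:
            return {g: "a" for g in labels}
        means = {g: values[groups == g].mean() for g in labels}
        distinct = sorted(set(means.values()), reverse=True)
        return {
            g: string.ascii_lowercase[distinct.index(means[g])]
            for g in labels
        }

    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    summary = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    differ = {
        frozenset((row["group1"], row["group2"]))
        for _, row in summary.iterrows()
        if row["reject"] is True or row["reject"] == "True"
    }

    # insert-absorb: maintain letter groups (sets of mutually compatible labels)
    letter_sets: list[set] = []
    for g in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in differ for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    out = {g: "" for g in labels}
    for letter, s in zip(string.ascii_lowercase, letter_sets):
        for g in labels:
            if g in s:
                out[g] += letter
    return out
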
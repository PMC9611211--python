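"""Tabular data model and TSV readers/writers.

The toolkit works on four kinds of tables, all carried as pandas objects:

* removal table   -- long format, one row per (system, pollutant, day,
                     replicate), value ``removal`` as a fraction in [0, 1];
* concentration table -- same keys with influent/effluent in mg/L;
* count table     -- taxon x sample integer counts with a lineage string per
                     taxon and a group label per sample (:class:`CountTable`);
* OD series       -- long format optical-density (680 nm) readings.

Long TSV with a header row is the canonical on-disk format; a wide removal
layout (pollutants as columns) is accepted on read and melted to long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RangeError",
    "RANKS",
    "CountTable",
    "validate_removal_table",
    "read_removal_table",
    "write_removal_table",
    "read_concentration_table",
    "removal_from_concentrations",
    "read_count_table",
    "read_od_series",
    "write_od_series",
    "aggregate_lineage",
    "relative_abundance",
]


class SchemaError(ValueError):
    """A required column is missing or a table is structurally invalid."""


class RangeError(ValueError):
    """A value lies outside its documented domain."""


REMOVAL_COLUMNS = ["system", "pollutant", "day", "replicate", "removal"]
CONCENTRATION_COLUMNS = [
    "system", "pollutant", "day", "replicate",
    "influent_mg_per_L", "effluent_mg_per_L",
]
OD_COLUMNS = ["system", "day", "replicate", "od680"]

#: Lineage ranks, outermost first.  Lineage strings are semicolon-delimited
#: and may stop early; missing ranks are treated as unclassified.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_GROUP_ROW = "#group"


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def validate_removal_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a long removal table.

    Returns a copy with canonical column order and integer day/replicate.
    Raises :class:`SchemaError` / :class:`RangeError` with the offending
    column or row named.
    """
    _require_columns(df, REMOVAL_COLUMNS, "removal table")
    out = df.loc[:, REMOVAL_COLUMNS].copy()
    out["day"] = out["day"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    out["removal"] = out["removal"].astype(float)

    bad = out.index[(out["removal"] < 0) | (out["removal"] > 1)]
    if len(bad):
        raise RangeError(
            f"removal outside [0, 1] at row(s) {list(bad[:5])} "
            f"(first offending value {out.loc[bad[0], 'removal']!r})"
        )
    if (out["day"] < 0).any():
        raise RangeError("day must be >= 0")
    if (out["replicate"] < 1).any():
        raise RangeError("replicate must be >= 1")
    keys = out[["system", "pollutant", "day", "replicate"]]
    if keys.duplicated().any():
        raise SchemaError("duplicate (system, pollutant, day, replicate) keys")
    return out.reset_index(drop=True)


def read_removal_table(path, dialect: str = "long_tsv") -> pd.DataFrame:
    """Read a removal table from TSV.

    ``dialect='long_tsv'`` expects the canonical five columns;
    ``dialect='wide_tsv'`` expects system/day/replicate plus one column per
    pollutant and melts to long.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "long_tsv":
        return validate_removal_table(df)
    if dialect == "wide_tsv":
        _require_columns(df, ["system", "day", "replicate"], "wide removal table")
        long = df.melt(
            id_vars=["system", "day", "replicate"],
            var_name="pollutant", value_name="removal",
        )
        return validate_removal_table(long)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_removal_table(df: pd.DataFrame, path) -> None:
    validate_removal_table(df).to_csv(path, sep="\t", index=False)


def read_concentration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CONCENTRATION_COLUMNS, "concentration table")
    return df.loc[:, CONCENTRATION_COLUMNS].copy()


def removal_from_concentrations(conc: pd.DataFrame) -> pd.DataFrame:
    """Convert influent/effluent concentrations to removal fractions.

    removal = (influent - effluent) / influent.  Negative removals (effluent
    transiently above influent) are clipped to 0 with a warning rather than
    rejected; influent must be strictly positive.
    """
    _require_columns(conc, CONCENTRATION_COLUMNS, "concentration table")
    influent = conc["influent_mg_per_L"].astype(float)
    effluent = conc["effluent_mg_per_L"].astype(float)
    if (influent <= 0).any():
        raise RangeError("influent_mg_per_L must be > 0")
    if (effluent < 0).any():
        raise RangeError("effluent_mg_per_L must be >= 0")
    removal = (influent - effluent) / influent
    if (removal < 0).any():
        n = int((removal < 0).sum())
        warnings.warn(
            f"{n} row(s) with effluent > influent; removal clipped to 0",
            stacklevel=2,
        )
        removal = removal.clip(lower=0.0)
    out = conc[["system", "pollutant", "day", "replicate"]].copy()
    out["removal"] = removal
    return validate_removal_table(out)


@dataclass
class CountTable:
    """Taxon-by-sample integer counts with lineages and sample groups.

    Attributes
    ----------
    counts : DataFrame, taxa (index) x samples (columns), non-negative ints.
    lineage : Series mapping taxon -> semicolon-delimited lineage string
        (kingdom;phylum;...;genus, at most 7 ranks; may stop early).
    groups : dict mapping each sample to its group label.
    """

    counts: pd.DataFrame
    lineage: pd.Series
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise RangeError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise SchemaError(f"samples without a group: {missing}")
        self.lineage = self.lineage.reindex(self.counts.index).fillna("")
        too_deep = self.lineage[self.lineage.str.count(";") + 1 > len(RANKS)]
        if len(too_deep):
            raise SchemaError(
                f"lineage with more than {len(RANKS)} ranks for "
                f"{list(too_deep.index[:3])}"
            )

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def group_of(self, sample: str) -> str:
        return self.groups[sample]

    def samples_in_group(self, group: str) -> list:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def to_tsv(self, path) -> None:
        """Write counts, lineages and groups as one TSV.

        The first data row, keyed ``#group``, carries each sample's group
        label so the file round-trips without a sidecar.
        """
        df = self.counts.copy()
        df.insert(0, "lineage", self.lineage)
        group_row = pd.DataFrame(
            [["" , *[self.groups[s] for s in self.counts.columns]]],
            index=pd.Index([_GROUP_ROW], name="taxon_id"),
            columns=df.columns,
        )
        pd.concat([group_row, df.rename_axis("taxon_id")]).to_csv(path, sep="\t")


def read_count_table(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "lineage" not in df.columns:
        raise SchemaError("count table is missing column(s): lineage")
    if _GROUP_ROW not in df.index:
        raise SchemaError("count table is missing the '#group' sample-group row")
    groups = df.loc[_GROUP_ROW].drop("lineage").to_dict()
    df = df.drop(index=_GROUP_ROW)
    lineage = df["lineage"].fillna("")
    counts = df.drop(columns="lineage").astype(int)
    return CountTable(counts=counts, lineage=lineage, groups=groups)


def read_od_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, OD_COLUMNS, "OD series")
    out = df.loc[:, OD_COLUMNS].copy()
    if (out["od680"] < 0).any():
        raise RangeError("od680 must be >= 0")
    return out


def write_od_series(df: pd.DataFrame, path) -> None:
    _require_columns(df, OD_COLUMNS, "OD series")
    df.loc[:, OD_COLUMNS].to_csv(path, sep="\t", index=False)


def _rank_label(lineage: str, rank_index: int) -> str:
    parts = [p.strip() for p in str(lineage).split(";")]
    if rank_index < len(parts) and parts[rank_index]:
        return parts[rank_index]
    return "unclassified"


def aggregate_lineage(table: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing a lineage rank (phylum, genus, ...).

    Taxa whose lineage does not resolve at ``rank`` are pooled under
    ``unclassified``.  Total counts per sample are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    idx = RANKS.index(rank)
    labels = table.lineage.map(lambda lin: _rank_label(lin, idx))
    counts = table.counts.groupby(labels.values).sum()
    counts.index.name = table.counts.index.name
    # keep the lineage prefix up to the aggregation rank
    lineage = pd.Series(
        {
            lab: ";".join(
                [_rank_label(table.lineage[labels[labels == lab].index[0]], i)
                 for i in range(idx + 1)]
            )
            for lab in counts.index
        }
    )
    return CountTable(counts=counts, lineage=lineage, groups=dict(table.groups))


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to 1."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise RangeError(f"sample(s) with zero total counts: {list(zero)}")
    return table.counts / totals
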
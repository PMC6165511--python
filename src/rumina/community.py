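"""Taxon table I/O, clade aggregation and diversity estimators.

The taxon table is a TSV with columns ``taxon_id``, ``lineage`` (semicolon
delimited, phylum first, at most 7 levels) followed by one column per sample.
Values are proportions of 16S rRNA gene sequences; count tables are accepted
and auto-normalised with the mode recorded.  Shannon diversity is reported in
natural-log units (nats); Chao1 and Good's coverage require integer counts
because they depend on singleton/doubleton frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLADE_LEVELS = ("phylum", "class", "order", "family", "genus", "species", "strain")
_SUM_TOL = 1e-6


class TaxonTableError(ValueError):
    """Raised when a taxon table violates the schema."""


@dataclass
class TaxonTable:
    """Samples x taxa proportions with a full lineage per taxon.

    ``data`` rows are samples, columns taxon ids.  ``lineages`` maps a taxon
    id to its ordered clade labels (phylum outermost).  ``mode`` records
    whether the source file held proportions or counts.
    """

    data: pd.DataFrame
    lineages: dict[str, tuple[str, ...]]
    mode: str = "proportions"
    counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.lineages)
        if missing:
            raise TaxonTableError(f"taxa without lineage: {sorted(missing)[:5]}")
        if (self.data.values < 0).any():
            raise TaxonTableError("negative abundance values")
        sums = self.data.sum(axis=1)
        bad = sums[(sums - 1).abs() > _SUM_TOL]
        if len(bad):
            raise TaxonTableError(
                f"sample proportions do not sum to 1: {list(bad.index[:5])}"
            )
        for tid, lin in self.lineages.items():
            if len(lin) > len(CLADE_LEVELS):
                raise TaxonTableError(
                    f"lineage for {tid!r} has {len(lin)} levels (max 7)"
                )
            if any(not lbl for lbl in lin):
                raise TaxonTableError(f"empty lineage label for {tid!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_levels(self) -> int:
        return max(len(v) for v in self.lineages.values())

    def lineage_strings(self) -> pd.Series:
        return pd.Series(
            {tid: ";".join(lin) for tid, lin in self.lineages.items()},
            name="lineage",
        )


def read_taxon_table(path) -> TaxonTable:
    """Read and validate a TSV taxon table; normalise counts if needed."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str},
                     float_precision="round_trip")
    if df.columns[0] != "taxon_id" or df.columns[1] != "lineage":
        raise TaxonTableError(
            "first two columns must be 'taxon_id' and 'lineage', got "
            f"{list(df.columns[:2])}"
        )
    if df["taxon_id"].duplicated().any():
        dups = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise TaxonTableError(f"duplicate taxon ids: {dups[:5]}")
    lineages = {}
    for tid, lin in zip(df["taxon_id"], df["lineage"]):
        if not isinstance(lin, str) or not lin.strip():
            raise TaxonTableError(f"malformed lineage for {tid!r}")
        lineages[str(tid)] = tuple(part.strip() for part in lin.split(";"))
    values = df.drop(columns=["taxon_id", "lineage"]).astype(float)
    values.index = df["taxon_id"].astype(str)
    data = values.T  # samples x taxa
    data.index.name = None
    data.columns.name = None
    if (data.values < 0).any():
        raise TaxonTableError("negative abundance values")

    sums = data.sum(axis=1)
    counts = None
    if np.allclose(sums, 1.0, atol=_SUM_TOL):
        mode = "proportions"
    else:
        arr = data.values
        if not np.allclose(arr, np.round(arr)):
            raise TaxonTableError(
                "table is neither proportions (rows sum to 1) nor integer counts"
            )
        mode = "counts"
        counts = data.round().astype(int)
        if (sums <= 0).any():
            raise TaxonTableError("count table contains empty samples")
        data = data.div(sums, axis=0)
    return TaxonTable(data=data, lineages=lineages, mode=mode, counts=counts)


def write_taxon_table(table: TaxonTable, path) -> None:
    out = table.data.T.copy()
    out.insert(0, "lineage", table.lineage_strings().reindex(out.index))
    out.index.name = "taxon_id"
    out.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class CladeMatrix:
    """Samples x clades matrix of proportions summed at one lineage level."""

    level: str
    data: pd.DataFrame


def aggregate_clade(table: TaxonTable, level: str) -> CladeMatrix:
    """Sum proportions over taxa sharing the lineage prefix at ``level``.

    Columns are named by the label at the requested level and ordered
    lexicographically; per-sample totals are preserved exactly (sums of the
    same addends).  Taxa whose lineage is shorter than the requested depth are
    carried under an explicit ``unclassified_<parent>`` placeholder.
    """
    if level not in CLADE_LEVELS:
        raise TaxonTableError(f"unknown clade level {level!r}")
    depth = CLADE_LEVELS.index(level) + 1
    if depth > table.n_levels:
        raise TaxonTableError(
            f"level {level!r} (depth {depth}) exceeds table depth {table.n_levels}"
        )
    labels = {}
    for tid, lin in table.lineages.items():
        if len(lin) >= depth:
            labels[tid] = lin[depth - 1]
        else:
            labels[tid] = f"unclassified_{lin[-1]}"
    grouped = table.data.T.groupby(pd.Series(labels)).sum().T
    grouped = grouped.reindex(sorted(grouped.columns), axis=1)
    return CladeMatrix(level=level, data=grouped)


def shannon(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats.

    Accepts any non-negative vector; it is renormalised to sum to one.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise TaxonTableError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise TaxonTableError("all-zero abundance vector")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise TaxonTableError("empty counts vector")
    if not np.issubdtype(arr.dtype, np.integer):
        as_float = np.asarray(arr, dtype=float)
        if not np.allclose(as_float, np.round(as_float)):
            raise TaxonTableError("integer counts required")
        arr = np.round(as_float).astype(np.int64)
    if np.any(arr < 0):
        raise TaxonTableError("counts must be non-negative")
    return arr


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    Uses ``S_obs + F1^2 / (2 F2)`` when doubletons exist and the
    bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` when F2 = 0.
    """
    arr = _check_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (fraction of sequences from seen taxa)."""
    arr = _check_counts(counts)
    n = int(arr.sum())
    if n <= 0:
        raise TaxonTableError("sample has no sequences")
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / n


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample S_obs, Shannon, Chao1 and Good's coverage from counts."""
    rows = {}
    for sample, vec in counts.iterrows():
        arr = _check_counts(vec.to_numpy())
        rows[sample] = {
            "s_obs": int((arr > 0).sum()),
            "shannon": shannon(arr),
            "chao1": chao1(arr),
            "goods_coverage": goods_coverage(arr),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def uniform_shannon(s: int) -> float:
    """Closed form ln(S) for a uniform community; used as an oracle."""
    return math.log(s)
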
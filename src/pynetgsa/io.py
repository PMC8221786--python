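"""Readers, writers and validation for interaction edge lists, pathway sets
and expression matrices.

All downstream matrices share a single canonical gene order, fixed by the
expression matrix: genes in pathways or edges that are absent from the
expression data are dropped (with a logged list), while expressed genes with
no known interactions are kept as isolated network nodes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("pynetgsa")

__all__ = [
    "ParseError",
    "ValidationError",
    "EdgeList",
    "PathwaySet",
    "ExpressionDataset",
    "read_edge_list",
    "write_edge_list",
    "read_pathways_gmt",
    "write_pathways_gmt",
    "read_pathways_matrix",
    "read_expression",
    "harmonize",
]


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


class ValidationError(ValueError):
    """Input parsed but violates a structural requirement."""


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Curated 0/1 gene-gene interactions.

    ``records`` has columns ``src``, ``dst``, ``directed`` (bool) and
    ``origin`` (free-text database tag). Undirected edges are stored once in
    canonical ``(min, max)`` identifier order; self-loops are removed and
    duplicate (src, dst, directed) triples collapse to a single record.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["src", "dst", "directed", "origin"]
        )
    )

    def __post_init__(self) -> None:
        self.records = _validate_edge_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def directed(self) -> bool:
        """True when the list contains any directed edge."""
        return bool(self.records["directed"].any())

    @property
    def genes(self) -> pd.Index:
        return pd.Index(
            sorted(set(self.records["src"]) | set(self.records["dst"]))
        )

    def restrict(self, universe: Iterable[str]) -> "EdgeList":
        """Drop edges with an endpoint outside ``universe`` (logged)."""
        keep = set(universe)
        rec = self.records
        mask = rec["src"].isin(keep) & rec["dst"].isin(keep)
        lost = sorted(
            (set(rec.loc[~mask, "src"]) | set(rec.loc[~mask, "dst"])) - keep
        )
        if lost:
            logger.info(
                "dropping %d edge-list genes absent from expression: %s",
                len(lost), ", ".join(lost[:20]),
            )
        return EdgeList(rec.loc[mask].reset_index(drop=True))


def _validate_edge_records(rec: pd.DataFrame) -> pd.DataFrame:
    rec = rec.copy()
    for col, default in (("directed", False), ("origin", "")):
        if col not in rec.columns:
            rec[col] = default
    rec = rec[["src", "dst", "directed", "origin"]]
    rec["src"] = rec["src"].astype(str)
    rec["dst"] = rec["dst"].astype(str)
    rec["directed"] = rec["directed"].astype(bool)
    if ((rec["src"] == "") | (rec["dst"] == "")).any():
        raise ValidationError("edge list contains empty gene identifiers")
    loops = rec["src"] == rec["dst"]
    if loops.any():
        logger.warning("dropped %d self-loop edge(s)", int(loops.sum()))
        rec = rec.loc[~loops]
    undirected = ~rec["directed"]
    lo = rec[["src", "dst"]].min(axis=1)
    hi = rec[["src", "dst"]].max(axis=1)
    rec.loc[undirected, "src"] = lo[undirected]
    rec.loc[undirected, "dst"] = hi[undirected]
    rec = rec.drop_duplicates(subset=["src", "dst", "directed"])
    return rec.reset_index(drop=True)


def read_edge_list(
    path,
    directed_default: bool = False,
    coerce_mixed: bool = False,
) -> EdgeList:
    """Read a TSV edge list: ``src<TAB>dst[<TAB>directed][<TAB>origin]``.

    A header row starting with ``src`` is skipped. ``directed`` is 0/1 and
    defaults to ``directed_default``. Files mixing directed and undirected
    edges are rejected unless ``coerce_mixed`` is set, in which case every
    edge is coerced to undirected (the directed and undirected structures
    flow to different estimators and cannot be mixed).
    """
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "src":
                continue
            if len(row) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 tab-separated "
                    f"columns, got {len(row)}"
                )
            src, dst = row[0].strip(), row[1].strip()
            directed = directed_default
            if len(row) >= 3 and row[2].strip() != "":
                flag = row[2].strip()
                if flag not in {"0", "1"}:
                    raise ParseError(
                        f"{path}: line {lineno}: directed flag must be 0 or 1, "
                        f"got {flag!r}"
                    )
                directed = flag == "1"
            origin = row[3].strip() if len(row) >= 4 else ""
            rows.append((src, dst, directed, origin))
    if not rows:
        logger.warning("%s: empty edge list", path)
        return EdgeList()
    rec = pd.DataFrame(rows, columns=["src", "dst", "directed", "origin"])
    kinds = set(rec["directed"])
    if len(kinds) > 1:
        if not coerce_mixed:
            raise ValidationError(
                f"{path}: mixed directed/undirected edges; pass "
                "coerce_mixed=True to coerce all edges to undirected"
            )
        rec["directed"] = False
    return EdgeList(rec)


def write_edge_list(edges: EdgeList, path) -> None:
    rec = edges.records.copy()
    rec["directed"] = rec["directed"].astype(int)
    rec.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathway sets
# ---------------------------------------------------------------------------

@dataclass
class PathwaySet:
    """Pathway-by-gene 0/1 membership.

    ``membership`` rows are pathways, columns the gene universe; row ``p``
    is the indicator vector of pathway ``p``. Every pathway retains at least
    one member in the universe.
    """

    membership: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.membership
        vals = set(np.unique(m.to_numpy()))
        if not vals <= {0, 1}:
            raise ValidationError(
                f"membership entries must be 0/1, found {sorted(vals - {0, 1})}"
            )
        empty = m.sum(axis=1) == 0
        if empty.any():
            raise ValidationError(
                "pathways with no member genes in the universe: "
                + ", ".join(m.index[empty])
            )
        self.membership = m.astype(np.int8)

    def __len__(self) -> int:
        return len(self.membership)

    @property
    def names(self) -> list[str]:
        return list(self.membership.index)

    def sizes(self) -> pd.Series:
        return self.membership.sum(axis=1)

    def members(self, name: str) -> list[str]:
        row = self.membership.loc[name]
        return list(row.index[row == 1])

    def restrict(self, universe: pd.Index) -> "PathwaySet":
        """Restrict membership to ``universe``; empty pathways are dropped
        with a warning."""
        sub = self.membership.reindex(columns=universe, fill_value=0)
        empty = sub.sum(axis=1) == 0
        if empty.any():
            logger.warning(
                "dropping %d pathway(s) with no member in the gene universe: %s",
                int(empty.sum()), ", ".join(sub.index[empty][:10]),
            )
            sub = sub.loc[~empty]
        if sub.empty:
            raise ValidationError("no pathway intersects the gene universe")
        return PathwaySet(sub)


def read_pathways_gmt(path, universe: Iterable[str]) -> PathwaySet:
    """Read a GMT file (name, description, members...) restricted to
    ``universe``."""
    universe = pd.Index(universe)
    rows: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name = fields[0].strip()
            members = {f.strip() for f in fields[2:] if f.strip()}
            if name in rows:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate pathway name {name!r}"
                )
            rows[name] = members
    if not rows:
        raise ParseError(f"{path}: empty GMT file")
    memb = pd.DataFrame(
        [[int(g in mem) for g in universe] for mem in rows.values()],
        index=list(rows), columns=universe,
    )
    empty = memb.sum(axis=1) == 0
    if empty.any():
        logger.warning(
            "dropping %d pathway(s) entirely outside the gene universe: %s",
            int(empty.sum()), ", ".join(memb.index[empty][:10]),
        )
        memb = memb.loc[~empty]
    if memb.empty:
        raise ValidationError(f"{path}: no pathway intersects the universe")
    return PathwaySet(memb)


def write_pathways_gmt(pathways: PathwaySet, path) -> None:
    with open(path, "w") as fh:
        for name in pathways.names:
            fh.write("\t".join([name, "na", *pathways.members(name)]) + "\n")


def read_pathways_matrix(path, universe: Iterable[str]) -> PathwaySet:
    """Read a CSV 0/1 membership matrix with pathway rows and gene columns."""
    memb = pd.read_csv(path, index_col=0)
    return PathwaySet(memb).restrict(pd.Index(universe))


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Gene-by-sample expression with a sample-to-condition map.

    The row order of ``values`` is the canonical gene order shared by every
    downstream matrix. Requires >= 2 conditions with >= 3 samples each and
    no missing values.
    """

    values: pd.DataFrame
    condition_of: pd.Series

    def __post_init__(self) -> None:
        vals, cond = self.values, self.condition_of
        missing = [s for s in vals.columns if s not in cond.index]
        if missing:
            raise ValidationError(
                f"sample(s) missing from condition map: {', '.join(map(str, missing))}"
            )
        cond = cond.reindex(vals.columns)
        if vals.isna().any().any():
            g, s = next(
                (g, s) for s in vals.columns for g in vals.index
                if pd.isna(vals.at[g, s])
            )
            raise ValidationError(f"missing value at gene {g!r}, sample {s!r}")
        counts = cond.value_counts()
        if len(counts) < 2:
            raise ValidationError("need at least 2 distinct conditions")
        small = counts[counts < 3]
        if not small.empty:
            raise ValidationError(
                "conditions with fewer than 3 samples: "
                + ", ".join(f"{k} (n={v})" for k, v in small.items())
            )
        self.values = vals.astype(float)
        self.condition_of = cond

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition_of:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_k(self) -> dict[str, int]:
        counts = self.condition_of.value_counts()
        return {c: int(counts[c]) for c in self.conditions}

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def matrix(self, condition: str | None = None) -> np.ndarray:
        """Gene-by-sample array, optionally restricted to one condition."""
        if condition is None:
            return self.values.to_numpy()
        cols = self.condition_of.index[self.condition_of == condition]
        if len(cols) == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return self.values[cols].to_numpy()

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(genes)], self.condition_of)


def read_expression(path, condition_map) -> ExpressionDataset:
    """Read a delimited gene-by-sample matrix and a two-column
    ``sample<TAB>condition`` map."""
    raw = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    vals = raw.apply(pd.to_numeric, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any().any():
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        raise ParseError(
            f"{path}: non-numeric value {raw.at[g, s]!r} at gene {g!r}, "
            f"sample {s!r}"
        )
    if vals.isna().any().any():
        g = vals.index[vals.isna().any(axis=1)][0]
        s = vals.columns[vals.loc[g].isna()][0]
        raise ValidationError(f"{path}: missing value at gene {g!r}, sample {s!r}")
    cond = pd.read_csv(
        condition_map, sep="\t", header=None, names=["sample", "condition"],
        dtype=str, comment=None,
    )
    if len(cond) and cond.iloc[0, 0] == "sample":
        cond = cond.iloc[1:]
    cond_series = pd.Series(
        cond["condition"].values, index=cond["sample"].values, name="condition"
    )
    return ExpressionDataset(vals, cond_series)


def harmonize(
    data: ExpressionDataset,
    edges: EdgeList | None = None,
    pathways: PathwaySet | None = None,
) -> tuple[ExpressionDataset, EdgeList | None, PathwaySet | None]:
    """Align edge list and pathways to the expression gene universe.

    Expression defines the universe: edges and pathway members outside it are
    dropped (logged); expressed genes without interactions remain isolated.
    """
    universe = data.genes
    if edges is not None:
        edges = edges.restrict(universe)
    if pathways is not None:
        pathways = pathways.restrict(universe)
    return data, edges, pathways
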
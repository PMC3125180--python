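"""Readers and writers for every external table the pipeline touches.

The central container is :class:`PulldownMatrix`, a sparse map from
``(protein, bait, replicate, fraction)`` to an emPAI abundance value.
Sparsity is semantic: a missing key means "protein not observed in that
run", which is distinct from an explicit 0 and is never silently filled.

The canonical on-disk layout is a TSV with one protein-id column and one
abundance column per ``(bait, replicate, fraction)`` triple, headers
written as ``<bait>|r<rep>|f<frac>``.  Foreign layouts are accommodated
through :class:`PulldownDialect`.  No-bait control runs live in the same
matrix under the reserved bait id ``CONTROL_ID``.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("apmsnet")

#: Reserved bait id under which no-bait control runs are stored.
CONTROL_ID = "__CONTROL__"

Key = tuple[str, str, int, int]  # (protein, bait, replicate, fraction)


class FormatError(ValueError):
    """A malformed input table (bad header, duplicate row, bad numeric)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class PulldownMatrix:
    """Sparse (protein, bait, replicate, fraction) -> emPAI map.

    Parameters
    ----------
    entries
        Mapping of keys to non-negative emPAI values.  Absence of a key
        means "not observed".
    """

    entries: dict[Key, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if value < 0:
                raise ValueError(f"negative emPAI value {value!r} at {key}")

    # -- views ------------------------------------------------------------

    def baits(self, include_control: bool = False) -> list[str]:
        """Ordered bait ids present in the matrix (control excluded by default)."""
        seen = sorted({k[1] for k in self.entries})
        if not include_control:
            seen = [b for b in seen if b != CONTROL_ID]
        return seen

    def proteins(self) -> list[str]:
        return sorted({k[0] for k in self.entries})

    def replicates(self, bait_id: str) -> list[int]:
        reps = sorted({k[2] for k in self.entries if k[1] == bait_id})
        if not reps:
            raise KeyError(f"unknown bait id {bait_id!r}")
        return reps

    def fractions(self, bait_id: str) -> list[int]:
        return sorted({k[3] for k in self.entries if k[1] == bait_id})

    def get(self, protein: str, bait: str, replicate: int, fraction: int):
        """Value at a key, or None when not observed (never 0)."""
        return self.entries.get((protein, bait, replicate, fraction))

    def has_control(self) -> bool:
        return any(k[1] == CONTROL_ID for k in self.entries)

    def subset_bait(self, bait_id: str) -> dict[Key, float]:
        return {k: v for k, v in self.entries.items() if k[1] == bait_id}

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PulldownMatrix):
            return NotImplemented
        return self.entries == other.entries


@dataclass
class RoleAnnotation:
    """protein_id -> functional role label (e.g. a TIGR role category)."""

    roles: dict[str, str] = field(default_factory=dict)

    def get(self, protein_id: str) -> str | None:
        return self.roles.get(protein_id)

    def labels(self) -> list[str]:
        return sorted(set(self.roles.values()))

    def __len__(self) -> int:
        return len(self.roles)


@dataclass
class ExpressionMatrix:
    """Gene x condition matrix of normalized log2 ratios; NaN = missing."""

    values: pd.DataFrame  # index: genes, columns: conditions

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene rows: {dups}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate condition columns")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SimilarityHits:
    """Best similarity hit per (query, subject), BLAST-tabular style."""

    hits: pd.DataFrame  # columns: query, subject, evalue, bitscore (optional NaN)

    def __post_init__(self) -> None:
        required = {"query", "subject", "evalue"}
        missing = required - set(self.hits.columns)
        if missing:
            raise FormatError(f"similarity hits missing columns: {sorted(missing)}")
        if (self.hits["evalue"] < 0).any():
            raise FormatError("negative e-values")


# ---------------------------------------------------------------------------
# Pull-down tables
# ---------------------------------------------------------------------------

@dataclass
class PulldownDialect:
    """How pull-down table columns encode (bait, replicate, fraction).

    ``header_pattern`` must expose named groups ``bait``, ``rep`` and
    (unless ``premax``) ``frac``.  With ``premax=True`` the table stores one
    pre-maximized column per (bait, replicate) and fraction is fixed at 1.
    """

    sep: str = "\t"
    protein_column: str = "protein"
    header_pattern: str = r"^(?P<bait>.+)\|r(?P<rep>\d+)\|f(?P<frac>\d+)$"
    premax: bool = False

    def parse_header(self, column: str) -> tuple[str, int, int]:
        m = re.match(self.header_pattern, column)
        if not m:
            raise FormatError(f"unparsable abundance column header: {column!r}")
        groups = m.groupdict()
        frac = 1 if self.premax else int(groups["frac"])
        return groups["bait"], int(groups["rep"]), frac

    def format_header(self, bait: str, rep: int, frac: int) -> str:
        if self.premax:
            return f"{bait}|r{rep}"
        return f"{bait}|r{rep}|f{frac}"


def read_pulldown_table(stream: IO[str] | str, dialect: PulldownDialect | None = None) -> PulldownMatrix:
    """Parse a wide pull-down TSV/CSV into a sparse :class:`PulldownMatrix`.

    Empty cells are treated as "not observed" and produce no entry.
    Duplicate protein rows, negative values and malformed numerics are
    reported with their row/column coordinates.
    """
    dialect = dialect or PulldownDialect()
    df = pd.read_csv(stream, sep=dialect.sep, dtype=str, keep_default_na=False)
    if dialect.protein_column not in df.columns:
        raise FormatError(f"missing protein-id column {dialect.protein_column!r}")
    if df[dialect.protein_column].duplicated().any():
        dups = df[dialect.protein_column][df[dialect.protein_column].duplicated()].tolist()
        raise FormatError(f"duplicate protein rows: {dups}")

    keys = {c: dialect.parse_header(c) for c in df.columns if c != dialect.protein_column}
    entries: dict[Key, float] = {}
    for row_idx, row in df.iterrows():
        protein = row[dialect.protein_column]
        for col, (bait, rep, frac) in keys.items():
            cell = row[col].strip()
            if cell == "":
                continue
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"malformed numeric {cell!r} at row {row_idx + 2}, column {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"negative emPAI {value} at row {row_idx + 2}, column {col!r}"
                )
            entries[(protein, bait, rep, frac)] = value
    return PulldownMatrix(entries)


def write_pulldown_table(matrix: PulldownMatrix, stream: IO[str] | str,
                         dialect: PulldownDialect | None = None) -> None:
    """Write a :class:`PulldownMatrix` as a wide table with deterministic ordering.

    Columns are ordered lexicographically by (bait, replicate, fraction) and
    rows by protein id; unobserved cells stay empty, so a re-read reproduces
    the matrix exactly.
    """
    dialect = dialect or PulldownDialect()
    columns = sorted({(k[1], k[2], k[3]) for k in matrix.entries})
    proteins = matrix.proteins()
    data: dict[str, list[str]] = {dialect.protein_column: proteins}
    for bait, rep, frac in columns:
        header = dialect.format_header(bait, rep, frac)
        col = []
        for protein in proteins:
            v = matrix.entries.get((protein, bait, rep, frac))
            col.append("" if v is None else repr(float(v)))
        data[header] = col
    pd.DataFrame(data).to_csv(stream, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# Roles, expression, similarity hits
# ---------------------------------------------------------------------------

def read_roles(stream: IO[str] | str) -> RoleAnnotation:
    """Two-column TSV (protein, role); extra columns ignored with a warning."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("role file needs at least (protein, role) columns")
    if df.shape[1] > 2:
        logger.warning("role file: ignoring extra columns %s", list(df.columns[2:]))
    protein_col, role_col = df.columns[0], df.columns[1]
    if df[protein_col].duplicated().any():
        raise FormatError("duplicate protein rows in role file")
    roles = {
        str(p): str(r)
        for p, r in zip(df[protein_col], df[role_col])
        if pd.notna(r) and str(r) != ""
    }
    return RoleAnnotation(roles)


def write_roles(annotation: RoleAnnotation, stream: IO[str] | str) -> None:
    df = pd.DataFrame(sorted(annotation.roles.items()), columns=["protein", "role"])
    df.to_csv(stream, sep="\t", index=False)


def read_expression(stream: IO[str] | str) -> ExpressionMatrix:
    """Gene-rows x condition-columns TSV of log2 ratios; blanks become NaN."""
    df = pd.read_csv(stream, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression(matrix: ExpressionMatrix, stream: IO[str] | str) -> None:
    matrix.values.to_csv(stream, sep="\t", index_label="gene")


_OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(stream: IO[str] | str) -> SimilarityHits:
    """Read a tabular similarity-hit file, keeping the best row per pair.

    Accepts either a headered TSV with at least query/subject/evalue
    columns or a header-less 12-column BLAST outfmt-6 table.  For repeated
    (query, subject) pairs only the minimum-e-value row is retained.
    """
    if isinstance(stream, str):
        with open(stream, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = stream.read()
    first = text.splitlines()[0] if text.strip() else ""
    has_header = "query" in first and "evalue" in first
    buf = io.StringIO(text)
    if has_header:
        df = pd.read_csv(buf, sep="\t")
        extra = [c for c in df.columns if c not in {"query", "subject", "evalue", "bitscore"}]
        if extra:
            logger.warning("hit file: ignoring extra columns %s", extra)
    else:
        df = pd.read_csv(buf, sep="\t", header=None)
        if df.shape[1] == len(_OUTFMT6_COLUMNS):
            df.columns = _OUTFMT6_COLUMNS
        elif df.shape[1] >= 3:
            df.columns = ["query", "subject", "evalue"] + [
                f"extra{i}" for i in range(df.shape[1] - 3)
            ]
        else:
            raise FormatError("hit file needs at least query/subject/evalue columns")
    df = df.copy()
    df["query"] = df["query"].astype(str)
    df["subject"] = df["subject"].astype(str)
    try:
        df["evalue"] = df["evalue"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric e-value in hit file: {exc}") from None
    if "bitscore" not in df.columns:
        df["bitscore"] = np.nan
    df["bitscore"] = pd.to_numeric(df["bitscore"], errors="coerce")
    # best row per (query, subject): min evalue, ties to max bitscore
    df = df.sort_values(
        ["query", "subject", "evalue", "bitscore"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    df = df.drop_duplicates(["query", "subject"], keep="first").reset_index(drop=True)
    return SimilarityHits(df[["query", "subject", "evalue", "bitscore"]])


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("pajek_net", "sif", "graphml", "edge_tsv")

#: Arbitrary width given to dashed (equal-to-control) edges in Pajek output.
DASHED_EDGE_WIDTH = 0.001


def write_network(network, stream: IO[str] | str, format: str = "edge_tsv") -> None:
    """Export an interaction network.

    ``pajek_net`` carries pseudo-confidence scores as arc weights, with
    dashed (equal-to-control) edges written at the sentinel width 0.001;
    ``sif`` uses the relation ``pulls_down``; ``graphml`` carries the full
    node and edge attribute set; ``edge_tsv`` is a flat edge list.
    """
    from .network_metrics import InteractionNetwork  # local import: avoid cycle

    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if not isinstance(network, InteractionNetwork):
        raise TypeError("write_network expects an InteractionNetwork")

    own = isinstance(stream, str)
    fh = open(stream, "w", encoding="utf-8") if own else stream
    try:
        if format == "pajek_net":
            _write_pajek(network, fh)
        elif format == "sif":
            for bait, prey, _ in network.sorted_edges():
                fh.write(f"{bait}\tpulls_down\t{prey}\n")
        elif format == "edge_tsv":
            fh.write("bait\tprey\tscore\tdashed\treciprocal\tp_value\n")
            for bait, prey, attrs in network.sorted_edges():
                p = attrs.get("p_value")
                fh.write(
                    f"{bait}\t{prey}\t{float(attrs['score'])!r}\t{int(attrs['dashed'])}\t"
                    f"{int(attrs['reciprocal'])}\t{'' if p is None else repr(float(p))}\n"
                )
        elif format == "graphml":
            g = nx.DiGraph()
            for node, attrs in sorted(network.graph.nodes(data=True)):
                g.add_node(node, role=attrs.get("role") or "",
                           is_bait=bool(attrs.get("is_bait")),
                           bait_prominence=float(attrs.get("bait_prominence", 0.0)))
            for bait, prey, attrs in network.sorted_edges():
                p = attrs.get("p_value")
                g.add_edge(bait, prey, score=float(attrs["score"]),
                           dashed=bool(attrs["dashed"]),
                           reciprocal=bool(attrs["reciprocal"]),
                           p_value=float("nan") if p is None else float(p))
            for line in nx.generate_graphml(g):
                fh.write(line + "\n")
    finally:
        if own:
            fh.close()


def _write_pajek(network, fh: IO[str]) -> None:
    nodes = sorted(network.graph.nodes)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    fh.write(f"*Vertices {len(nodes)}\n")
    for n in nodes:
        fh.write(f'{index[n]} "{n}"\n')
    fh.write("*Arcs\n")
    for bait, prey, attrs in network.sorted_edges():
        weight = DASHED_EDGE_WIDTH if attrs["dashed"] else float(attrs["score"])
        fh.write(f"{index[bait]} {index[prey]} {weight!r}\n")
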
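"""Readers and writers for PPI edge lists, expression matrices and complex sets.

Conventions
-----------
* Protein/gene identifiers are case-sensitive opaque strings; no aliasing.
* Lines starting with ``#`` are comments; blank lines are skipped.
* A PPI network is an undirected simple :class:`networkx.Graph`; an optional
  per-edge confidence lives in the ``weight`` attribute and must be in [0, 1].
* An expression matrix is a :class:`pandas.DataFrame` with one row per gene
  and ``T`` numeric columns (time points), ``T >= 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexSet",
    "read_edge_list",
    "read_expression",
    "read_complexes",
    "write_complexes",
]


@dataclass
class ComplexSet:
    """An ordered collection of protein sets (predicted clusters or a benchmark).

    Duplicate member sets are permitted on read (they are flagged by
    :meth:`validate`), empty sets never are.
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.complexes]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def validate(self) -> None:
        """Raise on empty member sets; warn about exact duplicates."""
        seen: set[frozenset[str]] = set()
        dups = 0
        for c in self.complexes:
            if len(c) == 0:
                raise ValidationError("complex set contains an empty complex")
            if c in seen:
                dups += 1
            seen.add(c)
        if dups:
            logger.warning("complex set %r contains %d duplicate complexes", self.label, dups)

    def as_multiset(self) -> dict[frozenset[str], int]:
        out: dict[frozenset[str], int] = {}
        for c in self.complexes:
            out[c] = out.get(c, 0) + 1
        return out


def _iter_data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a 2- or 3-column (node1, node2[, weight]) edge list into a graph.

    Self-loops are dropped (count logged); duplicate edges are collapsed,
    keeping the maximum weight when weighted.  A first line whose third token
    is non-numeric in a 3-column file is treated as a header and skipped.
    """
    path = Path(path)
    g = nx.Graph()
    self_loops = 0
    dup_edges = 0
    any_weight = False
    first_data = True
    for lineno, line in _iter_data_lines(path):
        toks = line.split()
        if len(toks) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(toks)}")
        if first_data:
            first_data = False
            if len(toks) >= 3 and not _is_number(toks[2]):
                continue  # header row
        u, v = toks[0], toks[1]
        w: float | None = None
        if len(toks) >= 3:
            try:
                w = float(toks[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: weight {toks[2]!r} is not numeric") from exc
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            any_weight = True
        if u == v:
            self_loops += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            dup_edges += 1
            old = g[u][v].get("weight")
            if w is not None and (old is None or w > old):
                g[u][v]["weight"] = w
        else:
            if w is not None:
                g.add_edge(u, v, weight=w)
            else:
                g.add_edge(u, v)
    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    if dup_edges:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, dup_edges)
    if any_weight:
        # mixed files: lines lacking a weight default to full confidence
        for u, v, data in g.edges(data=True):
            data.setdefault("weight", 1.0)
    return g


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV of gene ID followed by T numeric expression values.

    All rows must have the same T (ragged input is rejected) and T >= 2.
    Later duplicate gene IDs override earlier ones with a warning.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    for lineno, line in _iter_data_lines(path):
        toks = line.split()
        if len(toks) < 3:
            raise ValidationError(
                f"{path}:{lineno}: need a gene ID plus at least 2 values, got {len(toks)} tokens"
            )
        gene, vals = toks[0], toks[1:]
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise ValidationError(
                f"{path}:{lineno}: row has {len(vals)} values, expected {width} (ragged input)"
            )
        try:
            row = [float(v) for v in vals]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric expression value") from exc
        ids.append(gene)
        rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: no expression rows found")
    df = pd.DataFrame(rows, index=ids, columns=[f"t{i}" for i in range(width or 0)])
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated(keep="last").sum())
        logger.warning("%s: %d duplicate gene ID(s); keeping the last occurrence", path, n_dup)
        df = df[~df.index.duplicated(keep="last")]
    return df


def read_complexes(path: str | Path, label: str = "") -> ComplexSet:
    """Read one complex per line (whitespace-separated protein IDs)."""
    path = Path(path)
    complexes: list[frozenset[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            complexes.append(frozenset(line.split()))
    cs = ComplexSet(complexes=complexes, label=label or path.stem)
    cs.validate()
    return cs


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line; members sorted for reproducible output."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in cs.complexes:
            fh.write(" ".join(sorted(c)) + "\n")


def write_edge_list(g: nx.Graph, path: str | Path, decimals: int = 6) -> None:
    """Write a 3-column (or 2-column if unweighted) TSV edge list."""
    path = Path(path)
    weighted = any("weight" in d for _, _, d in g.edges(data=True))
    with open(path, "w") as fh:
        for u, v in sorted((tuple(sorted(e)) for e in g.edges()), key=lambda e: e):
            if weighted:
                w = g[u][v].get("weight", 1.0)
                fh.write(f"{u}\t{v}\t{w:.{decimals}f}\n")
            else:
                fh.write(f"{u}\t{v}\n")
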
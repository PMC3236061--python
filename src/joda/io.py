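"""Readers and writers for the pipeline's plain-text formats.

All matrices travel as tab-separated text with a header row and the gene
(or probe / experiment) id in the first column; missing values are written
as ``NA``.  Topologies are two-column edge lists accompanied by a
one-column regulators file (so isolated nodes are representable); beliefs
are four-column TSV; gene sets use the standard GMT layout.  Parsers
validate strictly and report the file and line of each defect.

Probe-level tables are collapsed to gene level with the interquartile-range
rule: among probes mapping to one gene id, the probe with the largest IQR
across arrays survives.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .mixture import BeliefSet
from .pathway import PathwayTopology

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_topology",
    "write_topology",
    "read_beliefs",
    "write_beliefs",
    "read_gmt",
    "write_gmt",
    "read_ranked_list",
    "write_ranked_list",
    "read_truth",
    "write_truth",
    "dedup_by_iqr",
]

NA = "NA"
FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """A file violates its format contract; names the file and line."""

    def __init__(self, path, line_no: int | None, message: str) -> None:
        loc = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _rows(path) -> Iterable[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line.split("\t")


def _parse_value(path, line_no: int, cell: str) -> float:
    if cell == NA or cell == "":
        return np.nan
    try:
        return float(cell)
    except ValueError:
        raise ParseError(path, line_no, f"non-numeric cell {cell!r}") from None


# -- matrices --------------------------------------------------------------

def read_matrix(path, index_name: str = "gene") -> pd.DataFrame:
    """Read a TSV matrix with a header row and row ids in the first column."""
    header: list[str] | None = None
    ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for line_no, fields in _rows(path):
        if header is None:
            if len(fields) < 2:
                raise ParseError(path, line_no, "header must have >= 2 columns")
            header = fields[1:]
            if len(set(header)) != len(header):
                raise ParseError(path, line_no, "duplicate column ids in header")
            continue
        if len(fields) != len(header) + 1:
            raise ParseError(
                path, line_no,
                f"expected {len(header) + 1} fields, found {len(fields)}",
            )
        rid = fields[0]
        if rid in seen:
            raise ParseError(path, line_no, f"duplicate row id {rid!r}")
        seen.add(rid)
        ids.append(rid)
        values.append([_parse_value(path, line_no, c) for c in fields[1:]])
    if header is None:
        raise ParseError(path, None, "empty matrix file")
    df = pd.DataFrame(values, index=ids, columns=header, dtype=float)
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path, index_name: str = "gene") -> None:
    df.to_csv(
        path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT,
        index_label=index_name,
    )


# -- topologies ------------------------------------------------------------

def read_topology(edges_path, regulators_path, population: str) -> PathwayTopology:
    """Read a pathway topology from an edge list plus a regulators file."""
    regulators: list[str] = []
    for line_no, fields in _rows(regulators_path):
        if len(fields) != 1:
            raise ParseError(
                regulators_path, line_no,
                f"regulators file must have one column, found {len(fields)}",
            )
        if fields[0] in regulators:
            raise ParseError(
                regulators_path, line_no, f"duplicate regulator {fields[0]!r}"
            )
        regulators.append(fields[0])
    edges: list[tuple[str, str]] = []
    for line_no, fields in _rows(edges_path):
        if len(fields) != 2:
            raise ParseError(
                edges_path, line_no,
                f"edge list must have two columns, found {len(fields)}",
            )
        edges.append((fields[0], fields[1]))
    return PathwayTopology(
        population=population, regulators=tuple(regulators), edges=tuple(edges)
    )


def write_topology(topology: PathwayTopology, edges_path, regulators_path) -> None:
    with open(regulators_path, "wt", encoding="utf-8") as fh:
        for r in topology.regulators:
            fh.write(f"{r}\n")
    with open(edges_path, "wt", encoding="utf-8") as fh:
        fh.write("# parent\tchild\n")
        for u, v in topology.edges:
            fh.write(f"{u}\t{v}\n")


# -- beliefs ---------------------------------------------------------------

def read_beliefs(path, default_belief: float = 0.95) -> list[BeliefSet]:
    """Read known-target beliefs: TSV (population, regulator, gene[, belief]).

    The belief column is optional and defaults to 0.95.  Returns one
    :class:`BeliefSet` per (population, regulator) pair, in file order.
    """
    grouped: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    for line_no, fields in _rows(path):
        if len(fields) not in (3, 4):
            raise ParseError(
                path, line_no,
                f"beliefs need 3 or 4 columns, found {len(fields)}",
            )
        pop, reg, gene = fields[:3]
        belief = default_belief if len(fields) == 3 else _parse_value(
            path, line_no, fields[3]
        )
        if not 0.0 < belief < 1.0:
            raise ParseError(
                path, line_no, f"belief {belief} outside (0, 1)"
            )
        if gene in grouped[(pop, reg)]:
            raise ParseError(
                path, line_no,
                f"duplicate belief for gene {gene!r} ({pop}, {reg})",
            )
        grouped[(pop, reg)][gene] = belief
    return [
        BeliefSet(population=pop, regulator=reg, entries=entries,
                  default_belief=default_belief)
        for (pop, reg), entries in grouped.items()
    ]


def write_beliefs(belief_sets: list[BeliefSet], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# population\tregulator\tgene\tbelief\n")
        for bs in belief_sets:
            for gene, b in bs.entries.items():
                fh.write(f"{bs.population}\t{bs.regulator}\t{gene}\t{b:.6g}\n")


# -- gene sets (GMT) -------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets: dict[str, tuple[str, ...]] = {}
    for line_no, fields in _rows(path):
        if len(fields) < 3:
            raise ParseError(
                path, line_no,
                "GMT line needs name, description and >= 1 member",
            )
        name = fields[0]
        if name in sets:
            raise ParseError(path, line_no, f"duplicate set name {name!r}")
        sets[name] = tuple(fields[2:])
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or NA, *genes]) + "\n")


# -- ranked lists ----------------------------------------------------------

def read_ranked_list(path) -> pd.Series:
    ids: list[str] = []
    scores: list[float] = []
    for line_no, fields in _rows(path):
        if len(fields) != 2:
            raise ParseError(
                path, line_no,
                f"ranked list needs 2 columns, found {len(fields)}",
            )
        if fields[0] in ids:
            raise ParseError(path, line_no, f"duplicate gene id {fields[0]!r}")
        ids.append(fields[0])
        scores.append(_parse_value(path, line_no, fields[1]))
    return pd.Series(scores, index=ids, name="score")


def write_ranked_list(ranked: pd.Series, path) -> None:
    """Two-column (gene, score) file, consumable by preranked enrichment tools."""
    with open(path, "wt", encoding="utf-8") as fh:
        for gene, score in ranked.items():
            cell = NA if pd.isna(score) else FLOAT_FORMAT % score
            fh.write(f"{gene}\t{cell}\n")


# -- planted truth ---------------------------------------------------------

def read_truth(path) -> pd.DataFrame:
    rows = []
    for line_no, fields in _rows(path):
        if len(fields) != 4:
            raise ParseError(
                path, line_no,
                f"truth file needs 4 columns, found {len(fields)}",
            )
        gene, pop, reg, sign = fields
        if sign not in ("-1", "1", "+1"):
            raise ParseError(path, line_no, f"sign must be +/-1, got {sign!r}")
        rows.append((gene, pop, reg, int(sign)))
    return pd.DataFrame(rows, columns=["gene", "population", "regulator", "sign"])


def write_truth(truth: pd.DataFrame, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# gene\tpopulation\tregulator\tsign\n")
        for _, row in truth.iterrows():
            fh.write(
                f"{row['gene']}\t{row['population']}\t{row['regulator']}\t"
                f"{int(row['sign']):+d}\n"
            )


# -- probe deduplication ---------------------------------------------------

def dedup_by_iqr(
    table: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Collapse probe rows to one row per gene by maximum interquartile range.

    Probes absent from the map are dropped (no gene identifier); among
    probes sharing one gene id the probe with the largest IQR across the
    columns survives, ties broken by lexicographically smallest probe id.
    All-missing rows are dropped with a warning.

    Parameters
    ----------
    table:
        Probes x arrays table.
    probe_to_gene:
        Probe id -> gene id.
    quartile_method:
        Quantile interpolation passed to :func:`numpy.nanpercentile`
        (default ``"linear"``).
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene map")
    by_gene: dict[str, list[tuple[float, str]]] = defaultdict(list)
    n_unmapped = 0
    n_allmissing = 0
    for probe in table.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        row = table.loc[probe].to_numpy(dtype=float)
        if not np.isfinite(row).any():
            n_allmissing += 1
            continue
        q1, q3 = np.nanpercentile(row, [25, 75], method=quartile_method)
        by_gene[gene].append((float(q3 - q1), probe))
    if n_unmapped:
        logger.info("dropped %d probe(s) without a gene identifier", n_unmapped)
    if n_allmissing:
        warnings.warn(
            f"dropped {n_allmissing} all-missing probe row(s)", UserWarning
        )
    survivors: dict[str, str] = {}
    for gene, candidates in by_gene.items():
        # max IQR; tie -> lexicographically smallest probe id
        best = min(candidates, key=lambda t: (-t[0], t[1]))
        survivors[gene] = best[1]
    out = table.loc[[survivors[g] for g in survivors]]
    out.index = pd.Index(list(survivors), name="gene")
    return out
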
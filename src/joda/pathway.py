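"""Pathway topologies and the binary perturbation-propagation models built from them.

A pathway topology is a directed graph over the perturbed regulators of one
cell population, with an edge (u, v) meaning "u activates v".  Knocking a
regulator down silences it together with everything reachable downstream, so
the set of regulators *affected* by a knock-down experiment is the reflexive
transitive closure of the topology.  The closure, laid out as a binary
experiments x regulators incidence matrix, is the *pathway model*: entry 1 in
row ``Δv`` and column ``u`` says that perturbing ``v`` affects ``u``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MalformedTopologyError",
    "PathwayTopology",
    "PathwayModel",
    "ExperimentSet",
    "experiment_id",
    "build_model",
    "affecting_experiments",
]


class MalformedTopologyError(ValueError):
    """An edge endpoint does not belong to the declared regulator set."""


def experiment_id(population: str, regulator: str) -> str:
    """Identifier of the knock-down experiment of ``regulator`` in ``population``.

    The convention is population-prefixed, e.g. ``"d:ATM"`` for the ATM
    knock-down in the damaged cells.
    """
    return f"{population}:{regulator}"


@dataclass(frozen=True)
class PathwayTopology:
    """Directed activation graph over the regulators of one cell population.

    Parameters
    ----------
    population:
        Cell-population label (e.g. ``"h"`` or ``"d"``).
    regulators:
        All regulators, in the order matrices will be indexed.  Isolated
        nodes are allowed, so the list is given explicitly rather than
        inferred from the edges.
    edges:
        Directed activation edges ``(parent, child)``.  Cycles and multiple
        connected components are permitted.  Duplicates are dropped with a
        warning; self-loops are accepted (the closure is reflexive anyway).
    """

    population: str
    regulators: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.regulators)) != len(self.regulators):
            raise MalformedTopologyError(
                f"duplicate regulator names in topology for population "
                f"{self.population!r}"
            )
        known = set(self.regulators)
        seen: list[tuple[str, str]] = []
        for edge in self.edges:
            for endpoint in edge:
                if endpoint not in known:
                    raise MalformedTopologyError(
                        f"edge {edge[0]!r} -> {edge[1]!r} in population "
                        f"{self.population!r} references unknown regulator "
                        f"{endpoint!r}"
                    )
            if edge in seen:
                logger.warning(
                    "duplicate edge %r -> %r in population %r dropped",
                    edge[0], edge[1], self.population,
                )
            else:
                seen.append(edge)
        object.__setattr__(self, "edges", tuple(seen))

    def graph(self) -> nx.DiGraph:
        """The topology as a :class:`networkx.DiGraph` (nodes in input order)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.regulators)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class PathwayModel:
    """Binary experiments x regulators incidence matrix of the closed topology.

    Rows are knock-down experiments (one per regulator, labelled
    ``"<population>:<regulator>"``), columns are regulators; ``matrix.iloc[i, j]
    == 1`` iff regulator *j* is reachable from the row's perturbed regulator
    (including the empty path, so the diagonal is all ones).
    """

    population: str
    matrix: pd.DataFrame

    @property
    def regulators(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    @property
    def experiments(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="experiment")


@dataclass(frozen=True)
class ExperimentSet:
    """The experiments affecting one regulator in one population (E_{v,t})."""

    regulator: str
    population: str
    experiments: tuple[str, ...]


def build_model(topology: PathwayTopology) -> PathwayModel:
    """Build the pathway model: the reflexive transitive closure of a topology.

    The model predicts how perturbation effects propagate: an experiment
    affects its own regulator (reflexivity) and every regulator reachable
    downstream in the activation graph.

    Returns
    -------
    PathwayModel
        With rows/columns ordered as ``topology.regulators``.
    """
    closure = nx.transitive_closure(topology.graph(), reflexive=True)
    regs = list(topology.regulators)
    mat = pd.DataFrame(0, index=regs, columns=regs, dtype=int)
    for u, v in closure.edges:
        mat.loc[u, v] = 1
    mat.index = [experiment_id(topology.population, r) for r in regs]
    return PathwayModel(population=topology.population, matrix=mat)


def affecting_experiments(model: PathwayModel, regulator: str) -> ExperimentSet:
    """All experiments of the model's population that affect ``regulator``.

    These are the rows of the pathway model with a 1 in the regulator's
    column: the regulator's own knock-down plus the knock-downs of all its
    upstream activators.  The set is never empty (reflexivity).
    """
    if regulator not in model.matrix.columns:
        raise KeyError(
            f"regulator {regulator!r} not in model for population "
            f"{model.population!r}; known: {list(model.matrix.columns)}"
        )
    col = model.matrix[regulator]
    exps = tuple(col.index[col == 1])
    return ExperimentSet(
        regulator=regulator, population=model.population, experiments=exps
    )
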
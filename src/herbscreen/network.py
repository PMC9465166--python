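"""Bipartite herb-ingredient networks and degree-based candidate filtering.

The material-basis evidence for a herb is the set of known-active
ingredients it contains.  Edges are restricted to active ingredients and
split by herb status: herbs already known hepatoprotective form the
"hepatoprotective" network, everything else the "undetermined" network.
A herb's degree in the undetermined network counts its distinct active
ingredients; herbs at or above a threshold become screening candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .io import DataError, HerbIngredientEdges

logger = logging.getLogger(__name__)

HERB = "herb"
INGREDIENT = "ingredient"


@dataclass
class BipartiteNetwork:
    """A herb-ingredient graph with a kind tag."""

    graph: nx.Graph
    kind: str  # "hepatoprotective" or "undetermined"

    @property
    def herb_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == HERB}

    @property
    def ingredient_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == INGREDIENT}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class CandidateDegree:
    herb: str
    n_active_ingredients: int


def build_networks(
    edges: HerbIngredientEdges,
    active_ingredients: Iterable[str],
    hepato_herbs: Iterable[str],
) -> tuple[BipartiteNetwork, BipartiteNetwork]:
    """Split edges into the hepatoprotective and undetermined networks.

    Edges whose ingredient is not in ``active_ingredients`` are dropped
    (count logged).  Herbs named in ``hepato_herbs`` go to the
    hepatoprotective network; all other herbs to the undetermined one.
    """
    if not edges.edges:
        raise DataError("edge list is empty")
    active = set(active_ingredients)
    hepato = set(hepato_herbs)
    nets = {
        "hepatoprotective": nx.Graph(),
        "undetermined": nx.Graph(),
    }
    dropped = 0
    for herb, ing in sorted(edges.edges):
        if ing not in active:
            dropped += 1
            continue
        if herb == ing:
            raise DataError(f"herb and ingredient share the name {herb!r}")
        g = nets["hepatoprotective"] if herb in hepato else nets["undetermined"]
        g.add_node(herb, role=HERB, status="hepatoprotective" if herb in hepato
                   else "undetermined", bipartite=0)
        g.add_node(ing, role=INGREDIENT, bipartite=1)
        g.add_edge(herb, ing)
    if dropped:
        logger.info("dropped %d edges with non-active ingredients", dropped)
    return (
        BipartiteNetwork(nets["hepatoprotective"], "hepatoprotective"),
        BipartiteNetwork(nets["undetermined"], "undetermined"),
    )


def ingredient_degree(net: BipartiteNetwork) -> list[CandidateDegree]:
    """Distinct-active-ingredient count (herb-node degree), one per herb."""
    return sorted(
        (CandidateDegree(h, net.graph.degree(h)) for h in net.herb_nodes),
        key=lambda d: (-d.n_active_ingredients, d.herb),
    )


def filter_candidates(
    degrees: Iterable[CandidateDegree], min_count: int = 15
) -> list[CandidateDegree]:
    """Herbs with at least ``min_count`` active ingredients (inclusive),
    sorted by count descending then name."""
    if min_count < 1:
        raise DataError("min_count must be at least 1")
    return sorted(
        (d for d in degrees if d.n_active_ingredients >= min_count),
        key=lambda d: (-d.n_active_ingredients, d.herb),
    )


def export_network(net: BipartiteNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or GEXF with role/status attributes."""
    path = str(path)
    if fmt.lower() == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt.lower() == "gexf":
        nx.write_gexf(net.graph, path)
    else:
        raise DataError(f"unknown export format {fmt!r}")
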
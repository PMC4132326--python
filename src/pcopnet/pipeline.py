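"""End-to-end orchestration: matrix -> relationship table -> networks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .io import ExpressionMatrix, standardize
from .networks import (SkeletonNetwork, attach_halo, build_graphs,
                       cliques_of_cliques, enumerate_gene_cliques,
                       match_all_pairs)
from .scan import PairRelationship, ScanConfig, ScanState, scan_all, summarize

logger = logging.getLogger(__name__)


@dataclass
class NetworkResult:
    networks: list[SkeletonNetwork]
    coexpression: nx.Graph
    nonlinear: nx.Graph
    n_cliques: int
    n_isomorphic_pairs: int


def run_scan(matrix: ExpressionMatrix,
             config: ScanConfig | None = None
             ) -> tuple[list[PairRelationship], ScanState, dict]:
    """Standardize, scan all pairs, and return (table, state, summary)."""
    config = config or ScanConfig()
    std = standardize(matrix)
    table, state = scan_all(std, config)
    return table, state, summarize(table, state, config, std.n_genes)


def run_networks(table: list[PairRelationship],
                 min_clique: int = 3,
                 min_sets: int = 3,
                 min_skeleton_genes: int = 3) -> NetworkResult:
    """Build graphs, enumerate cliques, match them, assemble networks + halos."""
    coexpr, nonlin = build_graphs(table)
    cliques = enumerate_gene_cliques(nonlin, min_size=min_clique)
    pairs = match_all_pairs(cliques, coexpr)
    nets = cliques_of_cliques(cliques, pairs, min_sets=min_sets,
                              min_skeleton_genes=min_skeleton_genes)
    for net in nets:
        attach_halo(net, coexpr, table)
    logger.info("%d gene cliques, %d isomorphic pairs, %d networks",
                len(cliques), len(pairs), len(nets))
    return NetworkResult(nets, coexpr, nonlin, len(cliques), len(pairs))
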
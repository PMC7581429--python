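"""Intersection of inheritance candidates with expression evidence.

A gene is *concordantly* differentially expressed at a timepoint when it is
significant versus both parents with the same fold-change sign.  Final
candidates are genes carrying an inheritance call that are concordant at both
the undifferentiated (d0) and differentiated (d25) timepoints.  A
first-neighbor interaction subnetwork around the validated candidates is
extracted for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from chdprio.errors import ConfigError
from chdprio.genomic_io import (
    PROBAND_VS_FATHER,
    PROBAND_VS_MOTHER,
    DETRecord,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceConfig:
    max_adjusted_p: float = 0.05
    min_abs_log2fc: float = 1.0
    require_both_parents: bool = True
    require_timepoints: frozenset = frozenset({"d0", "d25"})

    def __post_init__(self):
        if not 0.0 < self.max_adjusted_p < 1.0:
            raise ConfigError("max_adjusted_p must be in (0,1)")


def concordant_dets(records: Iterable[DETRecord], timepoint: str,
                    config: Optional[ConcordanceConfig] = None) -> Set[str]:
    """Genes significant versus BOTH parents with the same fold-change sign.

    Significance requires adjusted_p < max_adjusted_p and
    |log2FC| >= min_abs_log2fc in each comparison.  Genes with only one
    comparison present are excluded and logged.
    """
    config = config or ConcordanceConfig()
    by_gene: dict = {}
    for rec in records:
        if rec.timepoint != timepoint:
            continue
        by_gene.setdefault(rec.gene, {})[rec.comparison] = rec
    out = set()
    for gene, comps in by_gene.items():
        vm = comps.get(PROBAND_VS_MOTHER)
        vf = comps.get(PROBAND_VS_FATHER)
        if vm is None or vf is None:
            if config.require_both_parents:
                log.info("gene %s has only one parental comparison at %s; "
                         "excluded from concordance", gene, timepoint)
                continue
        pair = [r for r in (vm, vf) if r is not None]
        if not all(r.adjusted_p < config.max_adjusted_p
                   and abs(r.log2_fold_change) >= config.min_abs_log2fc
                   for r in pair):
            continue
        signs = {r.log2_fold_change > 0 for r in pair}
        if len(signs) == 1 and all(r.log2_fold_change != 0 for r in pair):
            out.add(gene)
    return out


def intersect_candidates(calls: Sequence, det_d0: Set[str],
                         det_d25: Set[str]) -> List[str]:
    """Genes with an inheritance call AND concordant expression at both
    timepoints (sorted for deterministic output)."""
    call_genes = {c.gene for c in calls}
    return sorted(call_genes & det_d0 & det_d25)


def first_neighbor_network(seed_genes: Iterable[str],
                           edges: Iterable[tuple]) -> Tuple[list, list]:
    """Induced subgraph on the seeds and their direct interactors.

    ``edges`` are (geneA, geneB, interaction_type) triples.  Self-loops are
    dropped and duplicate edges collapsed with the union of their types.
    Seeds absent from the edge list are retained as isolated nodes (warned).

    Returns (nodes, edge_list) with edge_list entries
    (geneA, geneB, sorted-type-tuple), genes ordered alphabetically.
    """
    seeds = set(seed_genes)
    g = nx.Graph()
    for a, b, etype in edges:
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["types"].add(etype)
        else:
            g.add_edge(a, b, types={etype})
    nodes = set()
    for s in seeds:
        nodes.add(s)
        if s in g:
            nodes.update(g.neighbors(s))
        else:
            log.warning("seed gene %s absent from the edge list; retained as "
                        "an isolated node", s)
    sub = g.subgraph(n for n in nodes if n in g)
    edge_list = sorted(
        (min(a, b), max(a, b), tuple(sorted(d["types"])))
        for a, b, d in sub.edges(data=True)
    )
    return sorted(nodes), edge_list
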
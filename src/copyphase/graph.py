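"""Transitive combination of pairwise constellations.

A pair that direct read evidence cannot resolve may still be phased through a
chain of resolved pairs via bridging events (other variants of the gene, or
nearby SNPs).  On a two-allele model the composition rule along a chain is
parity-like — an even number of ``diff`` links would put the endpoints on the
same allele — but once a chain contains two or more ``diff`` links the
presence of additional copies can no longer be excluded, so such chains are
conservatively ``undefined``:

    0 diff links -> same,  1 diff link -> diff,  >= 2 diff links -> undefined
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .phasing import Constellation

logger = logging.getLogger(__name__)

DEFAULT_MAX_CHAIN_LENGTH = 6


def compose_relations(chain: Sequence) -> str:
    """Relation of the endpoints of a chain of resolved constellations.

    Accepts relation strings or :class:`Constellation` objects.  The result
    depends only on the number of ``diff`` links, so it is invariant under
    chain reversal and link permutation.  An ``undefined`` link is a caller
    error: undefined is absorbing and must never be composed.
    """
    if not chain:
        raise ValueError("cannot compose an empty chain")
    relations = [c.relation if isinstance(c, Constellation) else c for c in chain]
    if any(r == "undefined" for r in relations):
        raise ValueError("chains must not contain undefined constellations")
    if any(r not in ("same", "diff") for r in relations):
        raise ValueError(f"unknown relation in chain: {relations}")
    n_diff = sum(r == "diff" for r in relations)
    if n_diff == 0:
        return "same"
    if n_diff == 1:
        return "diff"
    return "undefined"


@dataclass
class PhasingMatrix:
    """Symmetric pairwise relation matrix over the target variants.

    ``provenance`` records, per cell, the node chain the relation came from
    (just the two endpoints for directly observed pairs).
    """

    variants: List[str]
    cells: Dict[Tuple[str, str], Constellation] = field(default_factory=dict)
    provenance: Dict[Tuple[str, str], Tuple[str, ...]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> Constellation:
        if a == b:
            return Constellation(a, b, "same", 1.0, method="direct")
        cell = self.cells.get(self._key(a, b))
        if cell is None:
            return Constellation(a, b, "undefined", 0.0, method="imputed")
        return cell

    def set(self, constellation: Constellation, chain: Tuple[str, ...]) -> None:
        key = self._key(constellation.variant_a, constellation.variant_b)
        self.cells[key] = constellation
        self.provenance[key] = chain

    def chain(self, a: str, b: str) -> Tuple[str, ...]:
        return self.provenance.get(self._key(a, b), ())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations(self.variants, 2):
            cell = self.get(a, b)
            rows.append(
                {
                    "variant_a": a,
                    "variant_b": b,
                    "relation": cell.relation,
                    "confidence": cell.confidence,
                    "method": cell.method,
                    "chain": "->".join(self.chain(a, b)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["variant_a", "variant_b", "relation", "confidence", "method", "chain"],
        )


def _simple_paths(
    adjacency: Dict[str, Dict[str, Constellation]],
    start: str,
    goal: str,
    max_edges: int,
    forbidden_edge: Optional[Tuple[str, str]] = None,
) -> Iterable[Tuple[str, ...]]:
    """All simple paths start..goal with at most ``max_edges`` edges (DFS)."""
    stack: List[Tuple[str, Tuple[str, ...]]] = [(start, (start,))]
    while stack:
        node, path = stack.pop()
        if len(path) - 1 >= max_edges:
            continue
        for nxt in sorted(adjacency.get(node, {})):
            if nxt in path:
                continue
            if forbidden_edge and {node, nxt} == set(forbidden_edge):
                continue
            if nxt == goal:
                yield path + (nxt,)
            else:
                stack.append((nxt, path + (nxt,)))


def _path_stats(
    adjacency: Dict[str, Dict[str, Constellation]], path: Tuple[str, ...]
) -> Tuple[float, str, List[Tuple[str, str]]]:
    conf = 1.0
    relations = []
    edges = []
    for u, v in zip(path, path[1:]):
        cell = adjacency[u][v]
        conf *= cell.confidence
        relations.append(cell.relation)
        edges.append((u, v) if u <= v else (v, u))
    return conf, compose_relations(relations), edges


def infer_matrix(
    direct: Iterable[Constellation],
    targets: Sequence[str],
    max_chain_length: int = DEFAULT_MAX_CHAIN_LENGTH,
) -> PhasingMatrix:
    """Fill the pairwise matrix over ``targets``, imputing through bridges.

    Directly resolved pairs keep their observed relation; every unresolved
    target pair is searched for chains through resolved edges (bridging nodes
    such as SNPs are allowed but dropped from the output).  Among all simple
    paths up to ``max_chain_length`` edges, the highest-confidence one is
    reported (ties: shorter chain, then lexicographic node order); its
    composed relation may itself be ``undefined`` when it runs through two or
    more ``diff`` links.  Inconsistent cycles — a chain contradicting a
    directly observed edge — are logged, the direct edge wins for its own
    pair, and imputed cells relying on a tainted edge become undefined.
    """
    direct = list(direct)
    observed: Dict[Tuple[str, str], Constellation] = {}
    adjacency: Dict[str, Dict[str, Constellation]] = {}
    for cell in direct:
        key = PhasingMatrix._key(cell.variant_a, cell.variant_b)
        prev = observed.get(key)
        if prev is None or (
            prev.relation == "undefined" and cell.relation != "undefined"
        ):
            observed[key] = cell
        if cell.relation != "undefined":
            adjacency.setdefault(cell.variant_a, {})[cell.variant_b] = cell
            adjacency.setdefault(cell.variant_b, {})[cell.variant_a] = cell

    # detect cycles that contradict a directly observed edge
    tainted: set = set()
    for (a, b), cell in observed.items():
        if cell.relation == "undefined":
            continue
        for path in _simple_paths(adjacency, a, b, max_chain_length, forbidden_edge=(a, b)):
            _, relation, edges = _path_stats(adjacency, path)
            if relation != "undefined" and relation != cell.relation:
                logger.warning(
                    "inconsistent phasing cycle at %s-%s via %s; direct edge kept, "
                    "imputations through this cycle are undefined",
                    a, b, "->".join(path),
                )
                tainted.update(edges)
                tainted.add((a, b))

    matrix = PhasingMatrix(variants=list(targets))
    for a, b in itertools.combinations(targets, 2):
        key = PhasingMatrix._key(a, b)
        direct_cell = observed.get(key)
        if direct_cell is not None and direct_cell.relation != "undefined":
            matrix.set(direct_cell, (a, b))
            continue
        best = None  # (neg_conf, n_edges, path, relation)
        for path in _simple_paths(adjacency, a, b, max_chain_length):
            conf, relation, edges = _path_stats(adjacency, path)
            if any(e in tainted for e in edges):
                continue
            cand = (-conf, len(path) - 1, path, relation)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            matrix.set(Constellation(a, b, "undefined", 0.0, method="imputed"), (a, b))
            continue
        neg_conf, _, path, relation = best
        confidence = -neg_conf if relation != "undefined" else 0.0
        matrix.set(
            Constellation(a, b, relation, confidence, method="imputed"), path
        )
    return matrix
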
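"""Statistical-parsimony haplotype networks with a probability-based
connection limit.

Haplotypes are joined in increasing order of mutational distance up to the
largest number of steps that is "parsimonious" (free of superimposed
changes) with probability at least ``alpha`` (conventionally 95%).  Edges
spanning more than one change are expanded with inferred intermediate
haplotypes so that every edge in the final graph represents exactly one
nucleotide change.  Alternative equal-length connections are retained, so
the result is a minimum-spanning *network* (loops allowed), mirroring the
reticulations statistical-parsimony software draws.

Probability of parsimony.  For two sequences of length L differing at j
sites, per-site mutation counts are modelled as Poisson with mean
lambda(j), the Jukes-Cantor divergence re-estimated from j
(lambda = -(3/4) ln(1 - 4j/(3L))).  A j-step connection is parsimonious
when every differing site carries exactly one change and every identical
site carries none:

    P(j) = [lambda e^-lambda / p(lambda)]^j  x  [e^-lambda / (1-p(lambda))]^(L-j)

with p(lambda) = (3/4)(1 - e^(-4 lambda / 3)) the JC probability that a
site differs.  P is 1 at j = 0 and decreases in j; the connection limit is
the largest j with P(j) >= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeTable

__all__ = [
    "HaploNetwork",
    "parsimony_probability",
    "parsimony_connection_limit",
    "build_network",
]


def parsimony_probability(L: int, j: int) -> float:
    """Probability that a j-step connection between sequences of length L
    is free of superimposed changes (see module docstring)."""
    if L <= 0:
        raise ValueError("L must be positive")
    if j == 0:
        return 1.0
    if j >= 0.75 * L:
        return 0.0
    p_obs = j / L
    lam = -0.75 * np.log1p(-(4.0 / 3.0) * p_obs)
    p = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * lam))
    logp = j * (np.log(lam) - lam - np.log(p)) + (L - j) * (-lam - np.log1p(-p))
    return float(np.exp(logp))


def parsimony_connection_limit(L: int, alpha: float = 0.95, max_j: int = 64) -> int:
    """Largest number of mutational steps j <= max_j whose probability of
    parsimony is at least ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    limit = 0
    for j in range(1, max_j + 1):
        if parsimony_probability(L, j) >= alpha:
            limit = j
        else:
            break
    return limit if limit > 0 else 0


def _hap_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotypes of unequal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class HaploNetwork:
    """Statistical-parsimony network over observed and inferred haplotypes.

    ``graph`` is a simple undirected graph whose every edge represents one
    nucleotide change; observed nodes (``H1..Hk``) carry ``frequency`` and
    per-population counts, inferred intermediates (``mv1..mvK``) have
    frequency 0.
    """

    graph: nx.Graph
    connection_limit: int

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def steps_between(self, u: str, v: str) -> int:
        """Mutational steps along the shortest path between two nodes."""
        return nx.shortest_path_length(self.graph, u, v)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def edge_list_frame(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v} for u, v in sorted(self.graph.edges())]
        return pd.DataFrame(rows, columns=["source", "target"])

    def population_table(self) -> pd.DataFrame:
        """Per-node population composition (for pie-chart plotting)."""
        rows = []
        for n, d in sorted(self.graph.nodes(data=True)):
            if not d["observed"]:
                continue
            for key, val in sorted(d.items()):
                if key.startswith("count_"):
                    rows.append({"node": n, "population": key[6:], "count": val})
        return pd.DataFrame(rows, columns=["node", "population", "count"])


def build_network(table: HaplotypeTable, limit: int) -> HaploNetwork:
    """Build the statistical-parsimony network for a haplotype table.

    Candidate haplotype pairs are processed in increasing mutational
    distance; within a distance class, ties are broken by higher product of
    haplotype frequencies, then lexicographic node ids.  A pair is joined
    only if its two haplotypes were in different components when the
    distance class opened, which retains all alternative equal-length
    connections (loops) and never adds shortcut edges.  Pairs beyond
    ``limit`` stay in separate components.  Edges longer than one step are
    expanded with inferred intermediates ``mv1..mvK`` named in insertion
    order; output is deterministic for a fixed input.
    """
    k = table.k
    g = nx.Graph()
    names = [f"H{i + 1}" for i in range(k)]
    totals = table.total_counts
    for i, name in enumerate(names):
        attrs = {
            "observed": True,
            "frequency": int(totals[i]),
            "sequence": table.haplotypes[i],
        }
        for jpop, pop in enumerate(table.populations):
            attrs[f"count_{pop}"] = int(table.counts[i, jpop])
        g.add_node(name, **attrs)
    if k == 1:
        return HaploNetwork(graph=g, connection_limit=limit)

    pairs = []
    for i, j in combinations(range(k), 2):
        d = _hap_distance(table.haplotypes[i], table.haplotypes[j])
        pairs.append((d, -int(totals[i]) * int(totals[j]), names[i], names[j], i, j))
    pairs.sort()

    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mv_counter = 0
    by_d: dict[int, list] = {}
    for rec in pairs:
        by_d.setdefault(rec[0], []).append(rec)

    for d in sorted(by_d):
        if d > limit:
            break
        snapshot = {i: find(i) for i in range(k)}
        added = []
        for _, _, u, v, i, j in by_d[d]:
            if snapshot[i] == snapshot[j]:
                continue
            # expand the connection into d single-step edges
            if d == 1:
                g.add_edge(u, v)
            else:
                prev = u
                for _step in range(d - 1):
                    mv_counter += 1
                    mv = f"mv{mv_counter}"
                    g.add_node(mv, observed=False, frequency=0, sequence="")
                    g.add_edge(prev, mv)
                    prev = mv
                g.add_edge(prev, v)
            added.append((i, j))
        for i, j in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return HaploNetwork(graph=g, connection_limit=limit)
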
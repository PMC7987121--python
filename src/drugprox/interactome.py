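"""Interactome container, distance queries, and degree-matched node sampling.

The interactome is modelled as an undirected simple graph whose nodes are
gene (or protein) identifiers and whose edges are physical molecular
interactions.  All distance statistics downstream are unweighted hop counts
on this graph.  Because proximity statistics are strongly biased by node
degree (hubs are close to everything), the null model resamples node sets
that match the originals in size *and* degree.  The :class:`DegreeBins`
scaffold realizes that: nodes are grouped into bins of (near-)equal degree,
each large enough that sampling within a bin is non-degenerate, and a random
counterpart of a module draws one node from the bin of each original member.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SamplingExhaustedError",
    "Interactome",
    "DegreeBins",
    "NodeModule",
    "load_interactome",
    "write_interactome",
    "shortest_path_lengths",
    "build_degree_bins",
    "sample_degree_matched",
    "load_gene_sets",
    "modules_from_gene_sets",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the expected TSV dialect."""


class SamplingExhaustedError(RuntimeError):
    """Raised when a degree bin is too small to supply a degree-matched draw."""


class Interactome:
    """Undirected simple graph of gene nodes with a frozen sorted index.

    Wraps a :class:`networkx.Graph` and caches a CSR adjacency matrix so
    that the hot operation of the pipeline -- "hop distance from every node
    to the nearest member of a set" -- runs through compiled sparse-graph
    code rather than per-node Python BFS.

    Parameters
    ----------
    graph:
        Simple undirected graph.  Self-loops are rejected; node identifiers
        must be non-empty strings (compared case-sensitively).
    """

    def __init__(self, graph: nx.Graph) -> None:
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("interactome must be a simple undirected graph")
        for u, v in graph.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
        self.graph = graph
        self._order: list[str] = sorted(graph.nodes)
        self._index: dict[str, int] = {n: i for i, n in enumerate(self._order)}
        if self._order:
            self._adj = nx.to_scipy_sparse_array(
                graph, nodelist=self._order, weight=None, format="csr"
            )
        else:
            self._adj = None

    # -- basic container protocol -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        """Node identifiers as a set."""
        return set(self._order)

    @property
    def node_order(self) -> tuple[str, ...]:
        """Nodes in the frozen (sorted) index order used by distance arrays."""
        return tuple(self._order)

    @property
    def degree(self) -> dict[str, int]:
        """Map node -> number of distinct neighbors."""
        return {n: d for n, d in self.graph.degree}

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def number_of_nodes(self) -> int:
        return len(self._order)

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def index(self, node: str) -> int:
        """Position of *node* in :attr:`node_order`; KeyError if absent."""
        return self._index[node]

    # -- distances ----------------------------------------------------------------
    def min_hop_distances(self, sources: Iterable[str]) -> np.ndarray:
        """Hop distance from every node to its nearest node in *sources*.

        Returns an array aligned with :attr:`node_order`; unreachable nodes
        get ``inf``.  This is the multi-source breadth-first search behind
        the closest-distance proximity measure: evaluated once per disease
        module it yields ``min_s d(t, s)`` for every candidate target ``t``.
        """
        idx = [self._index[s] for s in sources]
        if not idx:
            raise ValueError("sources must be non-empty")
        return dijkstra(self._adj, unweighted=True, indices=idx, min_only=True)


@dataclass(frozen=True)
class DegreeBins:
    """Partition of interactome nodes into contiguous-degree bins.

    ``bins`` is ordered by ascending degree; ``bin_of`` maps each node to
    its bin index.  Every bin holds at least ``min_bin_size`` nodes (except
    when the whole graph is smaller than that), achieved by greedily merging
    adjacent degree classes, so that degree-matched sampling never draws
    from a near-singleton pool.
    """

    bins: tuple[tuple[str, ...], ...]
    bin_of: Mapping[str, int]
    min_bin_size: int
    degree_ranges: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class NodeModule:
    """A named set of interactome nodes (drug-target module or disease module).

    ``dropped`` records input identifiers that were absent from the
    interactome and hence excluded from ``members``.
    """

    name: str
    members: frozenset[str]
    dropped: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.members & self.dropped:
            raise ValueError(f"module {self.name!r}: members and dropped overlap")


def load_interactome(path: str | Path, keep_largest_component: bool = True) -> Interactome:
    """Load an interactome from a 2+ column whitespace/tab-separated edge list.

    Lines starting with ``#`` and blank lines are skipped; extra columns are
    ignored.  Self-loops and duplicate edges are dropped (counted and
    logged).  With ``keep_largest_component`` (the default) only the largest
    connected component is retained -- proximity over a disconnected graph
    yields infinities -- with size ties broken by the lexicographically
    smallest node set.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 fields")
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if g.number_of_edges() == 0:
        raise FormatError(f"{path}: no valid edges found")
    n_removed = 0
    if keep_largest_component:
        comps = list(nx.connected_components(g))
        biggest = max(len(c) for c in comps)
        keep = min((c for c in comps if len(c) == biggest), key=lambda c: sorted(c))
        n_removed = g.number_of_nodes() - len(keep)
        if n_removed:
            g = g.subgraph(keep).copy()
    logger.info(
        "loaded interactome %s: %d nodes, %d edges (dropped %d self-loops, "
        "%d duplicate edges, %d nodes outside the largest component)",
        path.name, g.number_of_nodes(), g.number_of_edges(), n_self, n_dup, n_removed,
    )
    return Interactome(g)


def write_interactome(g: Interactome, path: str | Path) -> None:
    """Serialize as a sorted two-column TSV edge list (round-trips with load)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.graph.edges):
            fh.write(f"{u}\t{v}\n")


def shortest_path_lengths(
    g: Interactome, sources: Iterable[str]
) -> dict[tuple[str, str], int]:
    """Unweighted BFS distances ``(source, node) -> hops`` for each source.

    Pairs with no connecting path are absent from the map (callers treat
    them as infinite).
    """
    out: dict[tuple[str, str], int] = {}
    for s in sources:
        if s not in g:
            raise KeyError(f"source node {s!r} not in interactome")
        for v, d in nx.single_source_shortest_path_length(g.graph, s).items():
            out[(s, v)] = d
    return out


def build_degree_bins(g: Interactome, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes into ascending-degree bins of at least ``min_bin_size``.

    Degree classes are visited in ascending order and greedily accumulated
    until a bin reaches ``min_bin_size``; a trailing undersized bin is
    merged backward into its predecessor.  Within a bin, node degrees form a
    contiguous range of the degree values present in the graph.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    if g.number_of_nodes() == 0:
        raise ValueError("cannot bin an empty graph")
    by_degree: dict[int, list[str]] = defaultdict(list)
    for node, deg in g.degree.items():
        by_degree[deg].append(node)

    bins: list[list[str]] = []
    ranges: list[tuple[int, int]] = []
    current: list[str] = []
    lo: int | None = None
    for deg in sorted(by_degree):
        if lo is None:
            lo = deg
        current.extend(by_degree[deg])
        if len(current) >= min_bin_size:
            bins.append(sorted(current))
            ranges.append((lo, deg))
            current, lo = [], None
    if current:
        hi = max(g.degree[n] for n in current)
        if bins:
            bins[-1] = sorted(bins[-1] + current)
            ranges[-1] = (ranges[-1][0], hi)
        else:  # whole graph smaller than min_bin_size
            bins.append(sorted(current))
            ranges.append((lo, hi))  # type: ignore[arg-type]

    bin_of = {n: i for i, b in enumerate(bins) for n in b}
    return DegreeBins(
        bins=tuple(tuple(b) for b in bins),
        bin_of=bin_of,
        min_bin_size=min_bin_size,
        degree_ranges=tuple(ranges),
    )


def sample_degree_matched(
    g: Interactome,
    bins: DegreeBins,
    template: NodeModule | Iterable[str],
    rng: int | np.random.Generator,
    exclude: Iterable[str] = (),
) -> set[str]:
    """Draw a random node set with the size and degree profile of *template*.

    Each template member is replaced by a uniform draw from its degree bin;
    draws are without replacement within the returned set, so the result
    has exactly ``|template|`` distinct nodes.  Nodes in *exclude* are never
    drawn (used to keep the random drug and disease groups of one null
    repeat disjoint).  Deterministic given an integer seed.
    """
    members = template.members if isinstance(template, NodeModule) else set(template)
    if not members:
        raise ValueError("template must be non-empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    excluded = set(exclude)
    need = Counter(bins.bin_of[m] for m in members)
    out: set[str] = set()
    for b in sorted(need):
        pool = bins.bins[b]
        if excluded:
            pool = tuple(n for n in pool if n not in excluded)
        k = need[b]
        if len(pool) < k:
            raise SamplingExhaustedError(
                f"degree bin {b} (degrees {bins.degree_ranges[b][0]}-"
                f"{bins.degree_ranges[b][1]}) has {len(pool)} nodes but the "
                f"template maps {k} members to it; rebuild bins with a larger "
                "min_bin_size"
            )
        picks = rng.choice(len(pool), size=k, replace=False)
        out.update(pool[i] for i in picks)
    return out


def load_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a long-format TSV with header, columns ``(set_id, gene_id)``.

    Returns an insertion-ordered map set name -> genes.  Extra columns are
    ignored.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 columns (set_id, gene_id)")
    sets: dict[str, set[str]] = {}
    for set_id, gene_id in zip(df.iloc[:, 0], df.iloc[:, 1]):
        set_id, gene_id = str(set_id).strip(), str(gene_id).strip()
        if not set_id or not gene_id:
            continue
        sets.setdefault(set_id, set()).add(gene_id)
    if not sets:
        raise FormatError(f"{path}: no (set_id, gene_id) rows found")
    return sets


def modules_from_gene_sets(
    gene_sets: Mapping[str, set[str]], g: Interactome
) -> list[NodeModule]:
    """Map raw gene sets onto the interactome, dropping absent genes.

    Genes not found in the interactome are recorded in ``dropped`` with a
    logged warning; a module whose members all drop is excluded from the
    returned list entirely (it cannot participate in proximity computation).
    """
    modules: list[NodeModule] = []
    for name, genes in gene_sets.items():
        members = frozenset(x for x in genes if x in g)
        dropped = frozenset(genes) - members
        if dropped:
            logger.warning(
                "module %s: %d/%d genes not in interactome (dropped)",
                name, len(dropped), len(genes),
            )
        if not members:
            logger.warning("module %s: all genes dropped; excluding module", name)
            continue
        modules.append(NodeModule(name=name, members=members, dropped=dropped))
    return modules
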
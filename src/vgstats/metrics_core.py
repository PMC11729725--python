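"""Primitive per-node, per-edge and per-step profiles.

Everything downstream (the metric catalog, path tables, windows, pangenome
partitions) is assembled from the profiles computed here.  All profiles are
computable in one pass over the links plus one pass over the path steps, so
runtime is linear in nodes + edges + total steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .gfa_io import GFAValidationError, VariationGraph, canonicalize_link

__all__ = [
    "DegreeProfile",
    "DepthProfile",
    "EdgeProfile",
    "JumpProfile",
    "node_index",
    "degree_profile",
    "depth_profile",
    "edge_depth_profile",
    "jump_profile",
    "connected_components",
    "node_lengths",
    "nX",
]


def node_index(graph: VariationGraph) -> dict[str, int]:
    """Map node id -> dense index in segment insertion order."""
    return {nid: i for i, nid in enumerate(graph.segments)}


def node_lengths(graph: VariationGraph) -> np.ndarray:
    return np.fromiter(
        (s.length for s in graph.segments.values()), dtype=np.int64, count=len(graph.segments)
    )


@dataclass
class DegreeProfile:
    """Link-attachment counts per node, in segment insertion order.

    A canonical link (a,oa,b,ob) attaches once at a's outgoing end
    (out_degree if oa is +, in_degree if -) and once at b's incoming end
    (in_degree if ob is +, out_degree if -).  A self-loop contributes both
    attachments to the same node, so the degree handshake
    sum(degree) == 2 * edge_count always holds.
    """

    in_degree: np.ndarray
    out_degree: np.ndarray

    @property
    def degree(self) -> np.ndarray:
        return self.in_degree + self.out_degree


@dataclass
class DepthProfile:
    """Path-coverage statistics per node, in segment insertion order."""

    depth: np.ndarray  # total steps on the node, multiplicity counted
    similarity: np.ndarray  # distinct samples with >= 1 step on the node
    both_orientations: np.ndarray  # bool: traversed both + and - across paths


@dataclass
class EdgeProfile:
    """Traversal counts per canonical link (direction-agnostic)."""

    links: list
    edge_depth: np.ndarray


@dataclass
class JumpProfile:
    """Per-path node-id jumps between consecutive steps.

    A jump is |id(next) - id(prev)| on numeric ids; it is only meaningful on a
    sorted id space, which ``sortedness`` (fraction of strictly increasing
    adjacent pairs) diagnoses.
    """

    threshold: int
    jumps: dict[str, np.ndarray]  # path name -> |delta id| per adjacent pair
    monotone_pairs: dict[str, int]  # pairs with id strictly increasing

    @property
    def total_pairs(self) -> int:
        return sum(len(j) for j in self.jumps.values())

    @property
    def all_jumps(self) -> np.ndarray:
        if not self.jumps:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([np.asarray(j) for j in self.jumps.values()])

    @property
    def above_threshold(self) -> int:
        return int((self.all_jumps > self.threshold).sum())

    @property
    def sortedness(self) -> float:
        """Monotone-increase pairs over all adjacent pairs (NaN if no pairs)."""
        total = self.total_pairs
        if total == 0:
            return float("nan")
        return sum(self.monotone_pairs.values()) / total


def degree_profile(graph: VariationGraph) -> DegreeProfile:
    idx = node_index(graph)
    n = len(idx)
    in_deg = np.zeros(n, dtype=np.int64)
    out_deg = np.zeros(n, dtype=np.int64)
    for link in graph.links:
        a, b = idx[link.from_id], idx[link.to_id]
        if link.from_orient == "+":
            out_deg[a] += 1
        else:
            in_deg[a] += 1
        if link.to_orient == "+":
            in_deg[b] += 1
        else:
            out_deg[b] += 1
    return DegreeProfile(in_deg, out_deg)


def depth_profile(graph: VariationGraph) -> DepthProfile:
    idx = node_index(graph)
    n = len(idx)
    depth = np.zeros(n, dtype=np.int64)
    fwd = np.zeros(n, dtype=bool)
    rev = np.zeros(n, dtype=bool)
    samples = {s: i for i, s in enumerate(graph.samples)}
    # sample occupancy as a (samples x nodes) incidence; S is small in practice
    occupancy = np.zeros((len(samples), n), dtype=bool)
    for path in graph.paths:
        srow = samples[path.sample]
        for nid, orient in path.steps:
            i = idx[nid]
            depth[i] += 1
            occupancy[srow, i] = True
            if orient == "+":
                fwd[i] = True
            else:
                rev[i] = True
    similarity = occupancy.sum(axis=0).astype(np.int64)
    return DepthProfile(depth, similarity, fwd & rev)


def sample_node_incidence(graph: VariationGraph) -> tuple[list[str], np.ndarray]:
    """(sample labels, samples x nodes boolean occupancy matrix)."""
    idx = node_index(graph)
    samples = graph.samples
    srow = {s: i for i, s in enumerate(samples)}
    inc = np.zeros((len(samples), len(idx)), dtype=bool)
    for path in graph.paths:
        r = srow[path.sample]
        for nid, _ in path.steps:
            inc[r, idx[nid]] = True
    return samples, inc


def edge_depth_profile(graph: VariationGraph) -> EdgeProfile:
    """Count, per canonical link, the adjacent step pairs realizing it.

    Raises :class:`GFAValidationError` if some adjacent pair of steps has no
    backing link, naming the path and step index.
    """
    link_row = {l.key: i for i, l in enumerate(graph.links)}
    counts = np.zeros(len(graph.links), dtype=np.int64)
    for path in graph.paths:
        steps = path.steps
        for i in range(len(steps) - 1):
            (a, oa), (b, ob) = steps[i], steps[i + 1]
            key = canonicalize_link(a, oa, b, ob).key
            row = link_row.get(key)
            if row is None:
                raise GFAValidationError(
                    f"path {path.name}, step {i}: adjacency "
                    f"{a}{oa}->{b}{ob} has no backing link"
                )
            counts[row] += 1
    return EdgeProfile(list(graph.links), counts)


def jump_profile(graph: VariationGraph, threshold: int = 1000) -> JumpProfile:
    """Per-path |delta node id| between consecutive steps (numeric ids only)."""
    if not graph.id_numeric:
        raise GFAValidationError(
            "jump statistics need numeric node ids; run node2int first"
        )
    jumps: dict[str, np.ndarray] = {}
    monotone: dict[str, int] = {}
    for path in graph.paths:
        ids = np.fromiter((int(nid) for nid, _ in path.steps), dtype=np.int64)
        delta = np.diff(ids)
        jumps[path.name] = np.abs(delta)
        monotone[path.name] = int((delta > 0).sum())
    return JumpProfile(threshold, jumps, monotone)


def connected_components(graph: VariationGraph) -> tuple[np.ndarray, int, int]:
    """Components of the undirected node adjacency (orientation ignored).

    Returns (component label per node, component count, largest size).
    """
    n = len(graph.segments)
    if n == 0:
        return np.zeros(0, dtype=np.int64), 0, 0
    idx = node_index(graph)
    rows = np.fromiter((idx[l.from_id] for l in graph.links), dtype=np.int64)
    cols = np.fromiter((idx[l.to_id] for l in graph.links), dtype=np.int64)
    adj = coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    count, labels = _cc(adj, directed=False)
    largest = int(np.bincount(labels).max())
    return labels.astype(np.int64), int(count), largest


def nX(lengths, x: float) -> int:
    """Length at which descending cumulative length first reaches x% of total.

    The standard N50/N90 assembly statistic applied to node lengths.  Empty
    input yields 0.
    """
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    target = arr.sum() * (x / 100.0)
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, target, side="left")])
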
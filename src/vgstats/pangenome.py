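"""Sample-level pangenome analytics.

Nodes are partitioned by occupancy (the number of distinct samples whose
paths traverse them) into core (all samples), shell (several), private
(exactly one) and absent (no path).  On top of the occupancy vector sit the
classical rarefaction genome-growth curves — the expected pangenome (union)
and core (intersection) content as a function of the number of samples drawn
— in an exact hypergeometric closed form and a permutation-sampled variant,
plus per-path occupancy profiles and a length-weighted Jaccard similarity
matrix between samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gfa_io import VariationGraph
from .metrics_core import node_index, node_lengths, sample_node_incidence

logger = logging.getLogger(__name__)

__all__ = [
    "PanClassification",
    "GrowthCurve",
    "classify_nodes",
    "growth_exact",
    "growth_permutation",
    "path_pangenome_profile",
    "sample_similarity_matrix",
]

CLASS_ABSENT = "absent"
CLASS_PRIVATE = "private"
CLASS_SHELL = "shell"
CLASS_CORE = "core"


@dataclass
class PanClassification:
    """Per-node occupancy and core/shell/private class.

    ``occupancy[i]`` is the number of distinct samples containing node i (in
    segment insertion order).  Classes: core == all S samples, private == 1,
    shell == 2..S-1, absent == 0.  For the degenerate S=1 graph every visited
    node satisfies both the core and the private rule; core takes precedence
    because "core" is defined relative to all samples present.  The softcore
    count (occupancy >= ceil(softcore_frac * S), core included) is reported
    alongside, not as a partition class.
    """

    node_ids: list[str]
    occupancy: np.ndarray
    classes: np.ndarray
    n_samples: int
    softcore_frac: float

    @property
    def softcore_count(self) -> int:
        cut = math.ceil(self.softcore_frac * self.n_samples)
        return int(((self.occupancy >= cut) & (self.occupancy >= 1)).sum())

    def count(self, cls: str) -> int:
        return int((self.classes == cls).sum())

    def bp(self, cls: str, lengths: np.ndarray) -> int:
        return int(lengths[self.classes == cls].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.node_ids, "occupancy": self.occupancy, "class": self.classes}
        )


def classify_nodes(graph: VariationGraph, softcore_frac: float = 0.95) -> PanClassification:
    """Classify every node by sample occupancy (distinct samples, not paths)."""
    samples, inc = sample_node_incidence(graph)
    s = len(samples)
    occ = inc.sum(axis=0).astype(np.int64)
    classes = np.full(occ.shape, CLASS_SHELL, dtype=object)
    classes[occ == 0] = CLASS_ABSENT
    classes[occ == 1] = CLASS_PRIVATE
    classes[occ == s] = CLASS_CORE  # wins over private when S == 1
    return PanClassification(list(graph.segments), occ, classes, s, softcore_frac)


@dataclass
class GrowthCurve:
    """Pan/core node- and bp-content as a function of samples drawn, k=1..S."""

    k: np.ndarray
    pan_nodes: np.ndarray
    pan_bp: np.ndarray
    core_nodes: np.ndarray
    core_bp: np.ndarray
    mode: str  # "exact" or "permutation"
    replicates: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "pan_nodes": self.pan_nodes,
                "pan_bp": self.pan_bp,
                "core_nodes": self.core_nodes,
                "core_bp": self.core_bp,
            }
        )


def growth_exact(graph: VariationGraph) -> GrowthCurve:
    """Closed-form rarefaction growth curve, exact over all k-subsets.

    With S samples and node occupancy s_v, averaging over all C(S,k) subsets
    of size k gives

        E[pan(k)]  = sum_v (1 - C(S - s_v, k) / C(S, k))
        E[core(k)] = sum_v C(s_v, k) / C(S, k)

    since a node is absent from a random k-subset's union iff all k samples
    avoid it, and in the intersection iff all k samples contain it.  bp
    variants weight each node by its length.  Binomials with upper < lower
    are zero.
    """
    cls = classify_nodes(graph)
    s = cls.n_samples
    occ = cls.occupancy
    lengths = node_lengths(graph).astype(float)
    ks = np.arange(1, s + 1)
    pan_n = np.zeros(s)
    pan_bp = np.zeros(s)
    core_n = np.zeros(s)
    core_bp = np.zeros(s)
    # occupancy takes few distinct values; aggregate nodes per value
    for s_v in np.unique(occ):
        mask = occ == s_v
        n_nodes = int(mask.sum())
        bp = float(lengths[mask].sum())
        for j, k in enumerate(ks):
            denom = math.comb(s, k)
            p_absent = math.comb(s - s_v, k) / denom if s - s_v >= k else 0.0
            p_core = math.comb(s_v, k) / denom if s_v >= k else 0.0
            pan_n[j] += n_nodes * (1.0 - p_absent)
            pan_bp[j] += bp * (1.0 - p_absent)
            core_n[j] += n_nodes * p_core
            core_bp[j] += bp * p_core
    return GrowthCurve(ks, pan_n, pan_bp, core_n, core_bp, mode="exact")


def growth_permutation(
    graph: VariationGraph, replicates: int = 100, seed: int = 0
) -> GrowthCurve:
    """Permutation-averaged growth curve.

    Each replicate shuffles the sample order with one seeded generator
    (consumed across replicates, so the run is reproducible end to end) and
    records cumulative-union (pan) and running-intersection (core) content at
    every prefix length k; per-k means over replicates are reported.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    samples, inc = sample_node_incidence(graph)
    s = len(samples)
    lengths = node_lengths(graph).astype(float)
    rng = np.random.default_rng(seed)
    pan_n = np.zeros(s)
    pan_bp = np.zeros(s)
    core_n = np.zeros(s)
    core_bp = np.zeros(s)
    for _ in range(replicates):
        order = rng.permutation(s)
        m = inc[order]
        union = np.logical_or.accumulate(m, axis=0)
        inter = np.logical_and.accumulate(m, axis=0)
        pan_n += union.sum(axis=1)
        pan_bp += union @ lengths
        core_n += inter.sum(axis=1)
        core_bp += inter @ lengths
    ks = np.arange(1, s + 1)
    r = float(replicates)
    return GrowthCurve(
        ks, pan_n / r, pan_bp / r, core_n / r, core_bp / r,
        mode="permutation", replicates=replicates, seed=seed,
    )


def path_pangenome_profile(graph: VariationGraph) -> pd.DataFrame:
    """Per-path bp at each occupancy level 1..S (multiplicity counted).

    Row sums equal each path's length in bp, so the table decomposes every
    haplotype into private/shared sequence the way stacked pangenome barplots
    do.
    """
    cls = classify_nodes(graph)
    idx = node_index(graph)
    lengths = node_lengths(graph)
    s = cls.n_samples
    rows = np.zeros((len(graph.paths), s), dtype=np.int64)
    for r, path in enumerate(graph.paths):
        for nid, _ in path.steps:
            i = idx[nid]
            rows[r, cls.occupancy[i] - 1] += lengths[i]
    return pd.DataFrame(
        rows, index=[p.name for p in graph.paths], columns=np.arange(1, s + 1)
    )


def sample_similarity_matrix(graph: VariationGraph) -> pd.DataFrame:
    """Length-weighted Jaccard similarity between samples' node sets.

    sim(i, j) = bp of shared nodes / bp of the union of the two node sets.
    The diagonal is 1 by definition; a sample with an empty node set gets 0
    against every other sample (with a warning).
    """
    samples, inc = sample_node_incidence(graph)
    lengths = node_lengths(graph).astype(float)
    weighted = inc * lengths  # (S, V)
    inter = weighted @ inc.T
    totals = weighted.sum(axis=1)
    union = totals[:, None] + totals[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "samples with empty node sets: %s", [s for s, e in zip(samples, empty) if e]
        )
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=samples, columns=samples)
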
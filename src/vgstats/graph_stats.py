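"""Graph-level metric catalog and per-path statistics table.

The catalog is a frozen, ordered set of 108 named metrics summarizing a
variation graph: size and composition, orientation and loops, node length,
degree, depth, node similarity, pangenome partition, node-id jumps, per-path
distributions and edge depth.  Adding, removing or reordering a metric is a
breaking change; ``METRIC_NAMES`` is the normative order.

Metrics that are undefined for a given graph (jump statistics on non-numeric
ids, distribution summaries of empty sets) are reported as missing — ``NA``
in TSV, ``null`` in JSON — so the 108-row shape is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics_core as mc
from . import pangenome as pg
from .gfa_io import VariationGraph

logger = logging.getLogger(__name__)

__all__ = ["MetricCatalog", "METRIC_NAMES", "graph_stats_report", "path_stats_table",
           "PATH_STATS_COLUMNS"]

_SUMM = ("mean", "median", "min", "max", "sd")

_G1 = [
    "node_count", "edge_count", "path_count", "sample_count",
    "graph_length_bp", "total_path_length_bp", "compression_ratio",
    "edges_per_node", "graph_density", "connected_components",
    "largest_component_nodes", "isolated_node_count",
]
_G2 = [
    "self_loop_count", "links_ff_count", "links_rr_count",
    "links_inverted_count", "links_inverted_frac", "nodes_both_orientations",
]
_G3 = [f"node_len_{s}" for s in _SUMM] + ["node_len_n50", "node_len_n90"]
_G4 = [f"{d}_{s}" for d in ("degree", "in_degree", "out_degree") for s in _SUMM]
_G5 = [f"depth_{s}" for s in _SUMM] + ["zero_depth_node_count"]
_G6 = [f"similarity_{s}" for s in _SUMM]
_G7 = [
    "private_node_count", "private_bp", "shell_node_count", "shell_bp",
    "core_node_count", "core_bp", "core_bp_frac", "private_bp_frac",
    "softcore_node_count",
]
_G8 = [
    "jump_total", "jump_mean", "jump_median", "jump_max", "jump_sd",
    "jumps_above_threshold", "jump_above_threshold_frac", "id_sortedness",
]
_PATH_FEATURES = (
    "path_length_bp", "path_step_count", "path_unique_node_count",
    "path_inverted_step_frac", "path_jump_total", "path_mean_degree",
    "path_mean_similarity",
)
_G9 = [f"{f}_{s}" for f in _PATH_FEATURES for s in _SUMM]
_G10 = [f"edge_depth_{s}" for s in _SUMM]

#: Frozen catalog order; exactly 108 names.
METRIC_NAMES: tuple[str, ...] = tuple(
    _G1 + _G2 + _G3 + _G4 + _G5 + _G6 + _G7 + _G8 + _G9 + _G10
)

#: Names whose values depend on the numeric node-id space.
JUMP_METRIC_NAMES: frozenset[str] = frozenset(_G8) | {
    f"path_jump_total_{s}" for s in _SUMM
}

PATH_STATS_COLUMNS = (
    "path_name", "sample", "length_bp", "step_count", "unique_node_count",
    "inverted_step_count", "inverted_step_frac", "jump_total", "jump_max",
    "jumps_above_threshold", "mean_depth", "mean_degree", "mean_similarity",
    "private_bp", "core_bp", "mean_node_length",
)


@dataclass
class MetricCatalog:
    """Ordered (name, value) pairs in the frozen 108-metric order."""

    entries: list[tuple[str, float | int | None]]

    def __post_init__(self) -> None:
        names = tuple(n for n, _ in self.entries)
        if names != METRIC_NAMES:
            raise ValueError("metric catalog names/order do not match METRIC_NAMES")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str):
        for n, v in self.entries:
            if n == name:
                return v
        raise KeyError(name)

    def as_dict(self) -> dict[str, float | int | None]:
        return dict(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["metric", "value"])


def _stats5(values) -> list[float | None]:
    """mean, median, min, max, population sd — or missing on empty input."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return [None] * 5
    return [
        float(arr.mean()), float(np.median(arr)), float(arr.min()),
        float(arr.max()), float(arr.std(ddof=0)),
    ]


def _ratio(num, den) -> float | None:
    return None if den == 0 else num / den


def graph_stats_report(graph: VariationGraph, jump_threshold: int = 1000) -> MetricCatalog:
    """Compute the full 108-metric catalog for one graph.

    Jump metrics need numeric node ids; on a graph with non-numeric ids they
    are reported as missing (with a warning) while every other group is still
    computed.
    """
    n = graph.node_count
    e = graph.edge_count
    lengths = mc.node_lengths(graph)
    deg = mc.degree_profile(graph)
    dep = mc.depth_profile(graph)
    cls = pg.classify_nodes(graph)
    _, n_components, largest = mc.connected_components(graph)
    path_table = path_stats_table(graph, jump_threshold)

    total_path_bp = int(path_table["length_bp"].sum()) if len(path_table) else 0
    graph_bp = graph.graph_length_bp

    self_loops = sum(1 for l in graph.links if l.is_self_loop)
    ff = sum(1 for l in graph.links if (l.from_orient, l.to_orient) == ("+", "+"))
    rr = sum(1 for l in graph.links if (l.from_orient, l.to_orient) == ("-", "-"))
    inverted = e - ff - rr

    values: dict[str, float | int | None] = {}
    values.update({
        "node_count": n,
        "edge_count": e,
        "path_count": graph.path_count,
        "sample_count": len(graph.samples),
        "graph_length_bp": graph_bp,
        "total_path_length_bp": total_path_bp,
        "compression_ratio": _ratio(total_path_bp, graph_bp),
        "edges_per_node": _ratio(e, n),
        "graph_density": _ratio(e - self_loops, n * (n - 1) / 2),
        "connected_components": n_components,
        "largest_component_nodes": largest,
        "isolated_node_count": int((deg.degree == 0).sum()),
    })
    values.update({
        "self_loop_count": self_loops,
        "links_ff_count": ff,
        "links_rr_count": rr,
        "links_inverted_count": inverted,
        "links_inverted_frac": _ratio(inverted, e),
        "nodes_both_orientations": int(dep.both_orientations.sum()),
    })
    for name, v in zip(_G3[:5], _stats5(lengths)):
        values[name] = v
    values["node_len_n50"] = mc.nX(lengths, 50)
    values["node_len_n90"] = mc.nX(lengths, 90)
    for arr, prefix in ((deg.degree, "degree"), (deg.in_degree, "in_degree"),
                        (deg.out_degree, "out_degree")):
        for s, v in zip(_SUMM, _stats5(arr)):
            values[f"{prefix}_{s}"] = v
    for s, v in zip(_SUMM, _stats5(dep.depth)):
        values[f"depth_{s}"] = v
    values["zero_depth_node_count"] = int((dep.depth == 0).sum())
    # similarity summaries cover visited nodes only: unvisited nodes belong
    # to no sample and would drag the distribution toward 0
    visited = dep.depth > 0
    for s, v in zip(_SUMM, _stats5(dep.similarity[visited])):
        values[f"similarity_{s}"] = v
    values.update({
        "private_node_count": cls.count(pg.CLASS_PRIVATE),
        "private_bp": cls.bp(pg.CLASS_PRIVATE, lengths),
        "shell_node_count": cls.count(pg.CLASS_SHELL),
        "shell_bp": cls.bp(pg.CLASS_SHELL, lengths),
        "core_node_count": cls.count(pg.CLASS_CORE),
        "core_bp": cls.bp(pg.CLASS_CORE, lengths),
        "core_bp_frac": _ratio(cls.bp(pg.CLASS_CORE, lengths), graph_bp),
        "private_bp_frac": _ratio(cls.bp(pg.CLASS_PRIVATE, lengths), graph_bp),
        "softcore_node_count": cls.softcore_count,
    })
    if graph.id_numeric:
        jp = mc.jump_profile(graph, jump_threshold)
        jumps = jp.all_jumps
        jump_stats = _stats5(jumps)
        values.update({
            "jump_total": int(jumps.sum()),
            "jump_mean": jump_stats[0],
            "jump_median": jump_stats[1],
            "jump_max": None if jumps.size == 0 else int(jumps.max()),
            "jump_sd": jump_stats[4],
            "jumps_above_threshold": jp.above_threshold,
            "jump_above_threshold_frac": _ratio(jp.above_threshold, jumps.size),
            "id_sortedness": None if jp.total_pairs == 0 else jp.sortedness,
        })
    else:
        logger.warning(
            "non-numeric node ids: jump metrics reported as NA; run node2int"
        )
        for name in _G8:
            values[name] = None
    for feature in _PATH_FEATURES:
        col = feature.removeprefix("path_")
        if feature == "path_jump_total":
            col = "jump_total"
        series = path_table[col].to_numpy(dtype=float) if len(path_table) else np.zeros(0)
        stats = [None] * 5 if np.isnan(series).any() else _stats5(series)
        for s, v in zip(_SUMM, stats):
            values[f"{feature}_{s}"] = v
    edge_prof = mc.edge_depth_profile(graph)
    for s, v in zip(_SUMM, _stats5(edge_prof.edge_depth)):
        values[f"edge_depth_{s}"] = v

    return MetricCatalog([(name, values[name]) for name in METRIC_NAMES])


def path_stats_table(graph: VariationGraph, jump_threshold: int = 1000) -> pd.DataFrame:
    """One row per path, in input order, with the 16 per-path statistics.

    Depth/degree/similarity means are taken over steps with multiplicity;
    private_bp and core_bp sum the lengths of steps landing on private/core
    nodes (again with multiplicity).  Jump columns are NaN when node ids are
    not numeric.
    """
    idx = mc.node_index(graph)
    lengths = mc.node_lengths(graph)
    deg = mc.degree_profile(graph).degree
    dep = mc.depth_profile(graph)
    cls = pg.classify_nodes(graph)
    numeric = graph.id_numeric
    jp = mc.jump_profile(graph, jump_threshold) if numeric else None

    rows = []
    for path in graph.paths:
        ix = np.fromiter((idx[nid] for nid, _ in path.steps), dtype=np.int64,
                         count=len(path.steps))
        inv = np.fromiter((o == "-" for _, o in path.steps), dtype=bool,
                          count=len(path.steps))
        step_lens = lengths[ix]
        length_bp = int(step_lens.sum())
        n_steps = len(ix)
        if numeric:
            jumps = jp.jumps[path.name]
            jump_total = int(jumps.sum())
            jump_max = int(jumps.max()) if jumps.size else 0
            jump_above = int((jumps > jump_threshold).sum())
        else:
            jump_total = jump_max = jump_above = np.nan
        step_classes = cls.classes[ix]
        rows.append({
            "path_name": path.name,
            "sample": path.sample,
            "length_bp": length_bp,
            "step_count": n_steps,
            "unique_node_count": int(np.unique(ix).size),
            "inverted_step_count": int(inv.sum()),
            "inverted_step_frac": float(inv.mean()),
            "jump_total": jump_total,
            "jump_max": jump_max,
            "jumps_above_threshold": jump_above,
            "mean_depth": float(dep.depth[ix].mean()),
            "mean_degree": float(deg[ix].mean()),
            "mean_similarity": float(dep.similarity[ix].mean()),
            "private_bp": int(step_lens[step_classes == pg.CLASS_PRIVATE].sum()),
            "core_bp": int(step_lens[step_classes == pg.CLASS_CORE].sum()),
            "mean_node_length": length_bp / n_steps,
        })
    return pd.DataFrame(rows, columns=list(PATH_STATS_COLUMNS))
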
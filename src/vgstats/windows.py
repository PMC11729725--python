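"""Path-centric sliding-window profiles.

A window slides along one path either in step units (node level) or in bp
(sequence level, every base inheriting the statistic of the node its step
covers).  Supported per-step statistics: depth, similarity, degree,
node_length, private_frac (fraction of steps/bases on occupancy-1 nodes) and
jump (numeric ids required).  Windows are 0-based half-open in path
coordinates; the trailing partial window is dropped by default so that all
reported values average the same amount of signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import metrics_core as mc
from . import pangenome as pg
from .gfa_io import GFAValidationError, VariationGraph

logger = logging.getLogger(__name__)

__all__ = ["WindowSpec", "STATISTICS", "sliding_windows", "project_path_coordinates"]

STATISTICS = ("depth", "similarity", "degree", "node_length", "private_frac", "jump")
MODES = ("steps", "bp")


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and statistic: mode (steps|bp), size, stride, statistic."""

    mode: str
    size: int
    step: int
    statistic: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown window statistic {self.statistic!r}")
        if self.size < 1:
            raise ValueError("window size must be >= 1")
        if not 1 <= self.step <= self.size:
            raise ValueError("stride must satisfy 1 <= step <= size")


def _per_step_statistic(graph: VariationGraph, spec: WindowSpec) -> dict[str, np.ndarray]:
    """Per-path arrays of the statistic, one value per step (jump: per pair)."""
    idx = mc.node_index(graph)
    if spec.statistic == "jump":
        if not graph.id_numeric:
            raise GFAValidationError(
                "window statistic 'jump' needs numeric node ids; run node2int"
            )
        jp = mc.jump_profile(graph)
        return {name: jumps.astype(float) for name, jumps in jp.jumps.items()}
    if spec.statistic == "node_length":
        per_node = mc.node_lengths(graph).astype(float)
    elif spec.statistic == "degree":
        per_node = mc.degree_profile(graph).degree.astype(float)
    elif spec.statistic == "private_frac":
        per_node = (pg.classify_nodes(graph).occupancy == 1).astype(float)
    else:
        dep = mc.depth_profile(graph)
        per_node = getattr(dep, spec.statistic).astype(float)
    out = {}
    for path in graph.paths:
        ix = np.fromiter((idx[nid] for nid, _ in path.steps), dtype=np.int64,
                         count=len(path.steps))
        out[path.name] = per_node[ix]
    return out


def _window_means(values: np.ndarray, size: int, stride: int,
                  keep_tail: bool) -> list[tuple[int, int, float]]:
    n = len(values)
    track = []
    cum = np.concatenate([[0.0], np.cumsum(values)])
    start = 0
    while start + size <= n:
        track.append((start, start + size, float((cum[start + size] - cum[start]) / size)))
        start += stride
    if keep_tail and start < n:
        width = n - start
        track.append((start, n, float((cum[n] - cum[start]) / width)))
    return track


def sliding_windows(
    graph: VariationGraph,
    spec: WindowSpec,
    paths: list[str] | None = None,
    keep_tail: bool = False,
) -> dict[str, list[tuple[int, int, float]]]:
    """Windowed means of a per-step statistic along each path.

    steps mode: the window value is the unweighted mean of the statistic over
    the steps inside the window; for ``jump`` it is the mean over the jumps
    whose left step falls inside the window (a window with no such jump
    yields 0).  bp mode: each base inherits its step's node statistic and the
    window averages over bases.  Orientation of a step does not change its
    contribution.

    Paths shorter than one window produce an empty track and a warning.  With
    ``keep_tail`` the final partial window is also emitted (shorter interval;
    callers can flag intervals with ``end - start < size``).
    """
    graph_paths = {p.name: p for p in graph.paths}
    if paths is None:
        selected = list(graph_paths)
    else:
        unknown = [n for n in paths if n not in graph_paths]
        if unknown:
            raise KeyError(f"unknown path(s): {', '.join(unknown)}")
        selected = list(paths)
    per_step = _per_step_statistic(graph, spec)
    idx = mc.node_index(graph)
    lengths = mc.node_lengths(graph)
    tracks: dict[str, list[tuple[int, int, float]]] = {}
    for name in selected:
        values = per_step[name]
        if spec.mode == "bp":
            path = graph_paths[name]
            step_lens = np.fromiter(
                (lengths[idx[nid]] for nid, _ in path.steps), dtype=np.int64,
                count=len(path.steps),
            )
            if spec.statistic == "jump":
                # a jump value sits between two steps; assign it to the bases
                # of its left step, last step excluded
                values = np.repeat(
                    np.concatenate([values, [0.0]]) if len(step_lens) else values,
                    step_lens,
                )
            else:
                values = np.repeat(values, step_lens)
        if len(values) < spec.size:
            logger.warning(
                "path %s shorter than one %s window (%d < %d): empty track",
                name, spec.mode, len(values), spec.size,
            )
            tracks[name] = []
            continue
        tracks[name] = _window_means(values, spec.size, spec.step, keep_tail)
    return tracks


def project_path_coordinates(graph: VariationGraph, path_name: str) -> np.ndarray:
    """Per-base node ids along one path (0-based; total length == path bp).

    Base i maps to the node of the step covering offset i.  Returns an int
    array when node ids are numeric, otherwise an object array of id strings.
    """
    for path in graph.paths:
        if path.name == path_name:
            break
    else:
        raise KeyError(f"unknown path {path_name!r}")
    ids = [nid for nid, _ in path.steps]
    reps = [graph.segments[nid].length for nid in ids]
    if graph.id_numeric:
        return np.repeat(np.array([int(i) for i in ids], dtype=np.int64), reps)
    return np.repeat(np.array(ids, dtype=object), reps)
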
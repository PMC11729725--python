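"""Synthetic variation graphs with recorded ground truth.

The simulator emits a GFAv1 graph built as an alternating chain of backbone
nodes and biallelic bubbles (SNP, insertion, deletion, inversion), one path
per sample, together with a :class:`TruthSheet` recording every node's sample
occupancy as constructed.  This gives each downstream statistic an exact
expected value without any external dataset.

Node ids are assigned 1..N in left-to-right chain order, so jump magnitudes
are small by construction; ``shuffle_ids`` permutes the labels (keeping
S-record order) to create high-jump / relabeling test cases.

Generation is fully deterministic for a given :class:`SimConfig`: the same
configuration, including its seed, reproduces the GFA text and the truth
byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SimConfig", "TruthSheet", "simulate_graph", "toy_graphs", "TOY1"]

_BASES = np.array(list("ACGT"))

BUBBLE_TYPES = ("snp", "insertion", "deletion", "inversion")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated pangenome graph.

    ``allele_freq`` is the per-bubble probability that a sample carries the
    alternative allele; with ``allele_freq_beta`` set, each bubble instead
    draws its frequency from Beta(a, b).  Default bubble mix leans on SNPs,
    the dominant variant class in real pangenomes, with a minority of small
    structural events.
    """

    n_samples: int = 4
    n_bubbles: int = 20
    backbone_len_range: tuple[int, int] = (5, 20)
    bubble_type_probs: dict = field(
        default_factory=lambda: {
            "snp": 0.6, "insertion": 0.15, "deletion": 0.15, "inversion": 0.1,
        }
    )
    allele_freq: float = 0.5
    allele_freq_beta: tuple[float, float] | None = None
    shuffle_ids: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be >= 0")
        total = sum(self.bubble_type_probs.get(t, 0.0) for t in BUBBLE_TYPES)
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("bubble type probabilities must sum to 1")
        if self.allele_freq_beta is None and not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be in (0, 1)")


@dataclass
class TruthSheet:
    """Ground truth recorded during construction.

    ``occupancy`` maps node id -> sorted list of samples whose path contains
    the node; ``classes`` the implied pangenome class (softcore fraction
    0.95); count fields summarize the partition; ``path_lengths_bp`` the per
    sample haplotype lengths.
    """

    node_count: int
    edge_count: int
    occupancy: dict[str, list[str]]
    classes: dict[str, str]
    private_node_count: int
    shell_node_count: int
    core_node_count: int
    absent_node_count: int
    path_lengths_bp: dict[str, int]

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)


def _class_of(occ: int, n_samples: int) -> str:
    if occ == 0:
        return "absent"
    if occ == n_samples:
        return "core"
    if occ == 1:
        return "private"
    return "shell"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_graph(config: SimConfig) -> tuple[str, TruthSheet]:
    """Build one synthetic graph; returns (GFAv1 text, TruthSheet).

    Chain layout: backbone node, bubble, backbone node, ... with
    ``n_bubbles`` bubbles and ``n_bubbles + 1`` backbone nodes.  Bubble
    realizations: snp — two alternative 1 bp nodes; insertion — an optional
    node versus a direct skip link; deletion — a node present in the
    reference allele that carriers skip; inversion — one node that allele
    carriers traverse in reverse orientation.  Every sample's path picks the
    alternative allele of each bubble independently with that bubble's
    frequency.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"s{i:02d}" for i in range(config.n_samples)]
    lo, hi = config.backbone_len_range

    next_id = 1

    def new_node(length: int) -> str:
        nonlocal next_id
        nid = str(next_id)
        next_id += 1
        segments[nid] = _random_seq(rng, length)
        return nid

    segments: dict[str, str] = {}
    links: list[tuple[str, str, str, str]] = []
    # per-sample step lists, built bubble by bubble
    steps: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}

    type_names = list(BUBBLE_TYPES)
    type_p = np.array([config.bubble_type_probs.get(t, 0.0) for t in type_names])

    prev = new_node(int(rng.integers(lo, hi + 1)))
    for s in samples:
        steps[s].append((prev, "+"))

    for _ in range(config.n_bubbles):
        btype = type_names[rng.choice(len(type_names), p=type_p)]
        if config.allele_freq_beta is not None:
            a, b = config.allele_freq_beta
            freq = float(rng.beta(a, b))
        else:
            freq = config.allele_freq
        alt = rng.random(config.n_samples) < freq
        nxt = None  # created after bubble nodes so ids stay in chain order
        if btype == "snp":
            ref_node = new_node(1)
            alt_node = new_node(1)
            nxt = new_node(int(rng.integers(lo, hi + 1)))
            links += [
                (prev, "+", ref_node, "+"), (prev, "+", alt_node, "+"),
                (ref_node, "+", nxt, "+"), (alt_node, "+", nxt, "+"),
            ]
            for s, is_alt in zip(samples, alt):
                steps[s].append((alt_node if is_alt else ref_node, "+"))
        elif btype == "insertion":
            ins = new_node(int(rng.integers(1, 11)))
            nxt = new_node(int(rng.integers(lo, hi + 1)))
            links += [
                (prev, "+", ins, "+"), (ins, "+", nxt, "+"), (prev, "+", nxt, "+"),
            ]
            for s, is_alt in zip(samples, alt):
                if is_alt:
                    steps[s].append((ins, "+"))
        elif btype == "deletion":
            dele = new_node(int(rng.integers(1, 11)))
            nxt = new_node(int(rng.integers(lo, hi + 1)))
            links += [
                (prev, "+", dele, "+"), (dele, "+", nxt, "+"), (prev, "+", nxt, "+"),
            ]
            for s, is_alt in zip(samples, alt):
                if not is_alt:
                    steps[s].append((dele, "+"))
        else:  # inversion
            inv = new_node(int(rng.integers(1, 11)))
            nxt = new_node(int(rng.integers(lo, hi + 1)))
            links += [
                (prev, "+", inv, "+"), (inv, "+", nxt, "+"),
                (prev, "+", inv, "-"), (inv, "-", nxt, "+"),
            ]
            for s, is_alt in zip(samples, alt):
                steps[s].append((inv, "-" if is_alt else "+"))
        for s in samples:
            steps[s].append((nxt, "+"))
        prev = nxt

    if config.shuffle_ids:
        perm = rng.permutation(len(segments)) + 1
        relabel = {old: str(new) for old, new in zip(segments, perm)}
        segments = {relabel[old]: seq for old, seq in segments.items()}
        links = [(relabel[a], oa, relabel[b], ob) for a, oa, b, ob in links]
        steps = {
            s: [(relabel[nid], orient) for nid, orient in path]
            for s, path in steps.items()
        }

    # ground truth straight from the constructed step lists
    occupancy: dict[str, set[str]] = {nid: set() for nid in segments}
    for s, path in steps.items():
        for nid, _ in path:
            occupancy[nid].add(s)
    classes = {
        nid: _class_of(len(occ), config.n_samples) for nid, occ in occupancy.items()
    }
    path_lengths = {
        s: sum(len(segments[nid]) for nid, _ in path) for s, path in steps.items()
    }
    # links are distinct by construction except inversion records when a
    # canonical duplicate slips in; count canonical-unique edges
    from .gfa_io import canonicalize_link

    canon = {canonicalize_link(a, oa, b, ob).key for a, oa, b, ob in links}
    truth = TruthSheet(
        node_count=len(segments),
        edge_count=len(canon),
        occupancy={nid: sorted(occ) for nid, occ in occupancy.items()},
        classes=classes,
        private_node_count=sum(c == "private" for c in classes.values()),
        shell_node_count=sum(c == "shell" for c in classes.values()),
        core_node_count=sum(c == "core" for c in classes.values()),
        absent_node_count=sum(c == "absent" for c in classes.values()),
        path_lengths_bp=path_lengths,
    )

    lines = ["H\tVN:Z:1.0"]
    for nid, seq in segments.items():
        lines.append(f"S\t{nid}\t{seq}")
    for a, oa, b, ob in links:
        lines.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M")
    for s in samples:
        body = ",".join(f"{nid}{orient}" for nid, orient in steps[s])
        lines.append(f"P\t{s}\t{body}\t*")
    return "\n".join(lines) + "\n", truth


TOY1 = """H\tVN:Z:1.0
S\t1\tACGT
S\t2\tA
S\t3\tC
S\t4\tGG
L\t1\t+\t2\t+\t0M
L\t1\t+\t3\t+\t0M
L\t2\t+\t4\t+\t0M
L\t3\t+\t4\t+\t0M
P\tx\t1+,2+,4+\t*
P\ty\t1+,3+,4+\t*
"""


def toy_graphs() -> dict[str, str]:
    """Named hand-checkable GFA fixtures, TOY1 plus degenerate corners."""
    return {
        "TOY1": TOY1,
        "empty": "H\tVN:Z:1.0\n",
        "single_node": "H\tVN:Z:1.0\nS\t1\tACGT\nP\tx\t1+\t*\n",
        "self_loop": (
            "H\tVN:Z:1.0\nS\t5\tACGT\nL\t5\t+\t5\t+\t0M\nP\tx\t5+,5+\t*\n"
        ),
        "isolated": TOY1 + "S\t9\tTTT\n",
        "single_sample": (
            "H\tVN:Z:1.0\nS\t1\tACGT\nS\t2\tA\nS\t3\tGG\n"
            "L\t1\t+\t2\t+\t0M\nL\t2\t+\t3\t+\t0M\n"
            "P\ts#1#chr1\t1+,2+,3+\t*\n"
        ),
        "inversion": (
            "H\tVN:Z:1.0\nS\t1\tACGT\nS\t2\tAC\nS\t3\tGG\n"
            "L\t1\t+\t2\t-\t0M\nL\t2\t-\t3\t+\t0M\n"
            "P\tx\t1+,2-,3+\t*\n"
        ),
    }
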
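"""Reading, validating, relabeling and writing GFAv1 variation graphs.

A variation graph is a bidirected sequence graph: nodes (segments) carry DNA
sequences, links join oriented segment ends, and named paths spell the input
haplotypes as ordered lists of oriented node traversals.  This module owns the
in-memory model (:class:`VariationGraph`) and the GFAv1 round trip.

Supported records: ``H`` (header), ``S`` (segment), ``L`` (link), ``P`` (path)
and ``W`` (walk, converted to a path).  ``C`` and unknown record types are
skipped with a warning.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, NamedTuple

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "Link",
    "PathRecord",
    "VariationGraph",
    "GFAError",
    "GFAParseError",
    "GFAValidationError",
    "canonicalize_link",
    "flip_orient",
    "parse_gfa",
    "parse_gfa_text",
    "write_gfa",
    "write_gfa_text",
    "node2int",
    "write_id_map",
]


class GFAError(Exception):
    """Base class for GFA format problems."""


class GFAParseError(GFAError):
    """A record could not be parsed (malformed mandatory columns)."""


class GFAValidationError(GFAError):
    """The parsed records are mutually inconsistent (dangling references...)."""


_ORIENTS = ("+", "-")

_NUMERIC_ID = re.compile(r"[1-9][0-9]*$")


def flip_orient(orient: str) -> str:
    """Reverse a traversal orientation (``+`` <-> ``-``)."""
    if orient == "+":
        return "-"
    if orient == "-":
        return "+"
    raise ValueError(f"invalid orientation {orient!r}")


@dataclass(frozen=True)
class Segment:
    """A graph node: identifier plus DNA sequence (or length-only stub)."""

    id: str
    sequence: str | None
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GFAValidationError(f"segment {self.id}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GFAValidationError(
                f"segment {self.id}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


class Link(NamedTuple):
    """A canonical bidirected edge between two oriented segment ends."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: str = "*"

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Edge identity: endpoints and orientations, overlap excluded."""
        return (self.from_id, self.from_orient, self.to_id, self.to_orient)

    @property
    def is_inverted(self) -> bool:
        """True when the two ends have mixed orientations."""
        return self.from_orient != self.to_orient

    @property
    def is_self_loop(self) -> bool:
        return self.from_id == self.to_id


def _id_sort_key(node_id: str) -> tuple[int, int, str]:
    # Numeric ids order numerically and before non-numeric ids; this keeps the
    # canonical form stable whether or not the graph has been through node2int.
    if _NUMERIC_ID.fullmatch(node_id):
        return (0, int(node_id), "")
    return (1, 0, node_id)


def _link_order_key(a: str, oa: str, b: str, ob: str):
    return (_id_sort_key(a), _ORIENTS.index(oa), _id_sort_key(b), _ORIENTS.index(ob))


def canonicalize_link(
    from_id: str, from_orient: str, to_id: str, to_orient: str, overlap: str = "*"
) -> Link:
    """Map a link and its reverse complement to one canonical representative.

    In a bidirected graph the records ``a,oa -> b,ob`` and
    ``b,flip(ob) -> a,flip(oa)`` describe the same edge.  The canonical form is
    the lexicographically smaller of the two under (id ascending, ``+`` before
    ``-``).
    """
    if from_orient not in _ORIENTS or to_orient not in _ORIENTS:
        raise ValueError(f"invalid orientation in link {from_id}{from_orient}->{to_id}{to_orient}")
    fwd = (from_id, from_orient, to_id, to_orient)
    rev = (to_id, flip_orient(to_orient), from_id, flip_orient(from_orient))
    best = min(fwd, rev, key=lambda t: _link_order_key(*t))
    return Link(*best, overlap)


@dataclass
class PathRecord:
    """A haplotype path: ordered oriented traversals of segments.

    The sample name follows the PanSN convention: everything before the first
    ``#`` of the path name, or the full name if no ``#`` is present.
    """

    name: str
    steps: list[tuple[str, str]]

    @property
    def sample(self) -> str:
        return self.name.split("#", 1)[0]

    @property
    def step_count(self) -> int:
        return len(self.steps)


@dataclass
class VariationGraph:
    """Segments, canonical links and named paths of one GFAv1 graph."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)
    paths: list[PathRecord] = field(default_factory=list)

    @property
    def id_numeric(self) -> bool:
        """True when every segment id parses as a positive integer."""
        return all(_NUMERIC_ID.fullmatch(s) for s in self.segments)

    @property
    def node_count(self) -> int:
        return len(self.segments)

    @property
    def edge_count(self) -> int:
        return len(self.links)

    @property
    def path_count(self) -> int:
        return len(self.paths)

    @property
    def samples(self) -> list[str]:
        """Distinct sample names in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.paths:
            seen.setdefault(p.sample, None)
        return list(seen)

    @property
    def graph_length_bp(self) -> int:
        return sum(s.length for s in self.segments.values())

    def path_length_bp(self, path: PathRecord) -> int:
        return sum(self.segments[nid].length for nid, _ in path.steps)

    def link_set(self) -> set[tuple[str, str, str, str]]:
        return {l.key for l in self.links}

    def validate(self) -> None:
        """Check referential integrity; raise :class:`GFAValidationError`."""
        names: set[str] = set()
        for path in self.paths:
            if path.name in names:
                raise GFAValidationError(f"duplicate path name {path.name}")
            names.add(path.name)
            if not path.steps:
                raise GFAValidationError(f"path {path.name} has no steps")
            for nid, orient in path.steps:
                if nid not in self.segments:
                    raise GFAValidationError(f"unknown segment in path {path.name}: {nid}")
                if orient not in _ORIENTS:
                    raise GFAValidationError(
                        f"invalid orientation {orient!r} in path {path.name}"
                    )
        for link in self.links:
            for end in (link.from_id, link.to_id):
                if end not in self.segments:
                    raise GFAValidationError(f"link references unknown segment {end}")

    def equivalent(self, other: "VariationGraph") -> bool:
        """Structural equality: segments, canonical edge set, paths in order."""
        if set(self.segments) != set(other.segments):
            return False
        for nid, seg in self.segments.items():
            o = other.segments[nid]
            if (seg.sequence, seg.length) != (o.sequence, o.length):
                return False
        if self.link_set() != other.link_set():
            return False
        if len(self.paths) != len(other.paths):
            return False
        return all(
            (a.name, a.steps) == (b.name, b.steps)
            for a, b in zip(self.paths, other.paths)
        )


# ---------------------------------------------------------------------------
# parsing


def _parse_tags(fields: Iterable[str]) -> dict[str, str]:
    tags: dict[str, str] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def _parse_segment(fields: list[str], lineno: int) -> Segment:
    if len(fields) < 3:
        raise GFAParseError(f"line {lineno}: S record needs id and sequence columns")
    seg_id, seq = fields[1], fields[2]
    if seq == "*":
        tags = _parse_tags(fields[3:])
        if "LN" not in tags:
            raise GFAParseError(
                f"line {lineno}: segment {seg_id} has sequence '*' and no LN:i: tag"
            )
        try:
            length = int(tags["LN"])
        except ValueError as exc:
            raise GFAParseError(f"line {lineno}: bad LN tag on segment {seg_id}") from exc
        return Segment(seg_id, None, length)
    return Segment(seg_id, seq.upper(), len(seq))


def _parse_link(fields: list[str], lineno: int) -> Link:
    if len(fields) < 5:
        raise GFAParseError(f"line {lineno}: L record needs 5 columns")
    overlap = fields[5] if len(fields) > 5 else "*"
    a, oa, b, ob = fields[1:5]
    if oa not in _ORIENTS or ob not in _ORIENTS:
        raise GFAParseError(f"line {lineno}: invalid link orientation")
    return canonicalize_link(a, oa, b, ob, overlap)


_STEP_RE = re.compile(r"([!-~]+?)([+-])$")


def _parse_path(fields: list[str], lineno: int) -> PathRecord:
    if len(fields) < 3:
        raise GFAParseError(f"line {lineno}: P record needs name and segment list")
    name = fields[1]
    steps: list[tuple[str, str]] = []
    for token in fields[2].split(","):
        m = _STEP_RE.fullmatch(token)
        if not m:
            raise GFAParseError(f"line {lineno}: bad path step {token!r} in path {name}")
        steps.append((m.group(1), m.group(2)))
    return PathRecord(name, steps)


_WALK_STEP_RE = re.compile(r"([><])([^><]+)")


def _parse_walk(fields: list[str], lineno: int) -> PathRecord:
    # W sample hap seqid start end walk  ->  path named sample#hap#seqid
    if len(fields) < 7:
        raise GFAParseError(f"line {lineno}: W record needs 7 columns")
    sample, hap, seqid, walk = fields[1], fields[2], fields[3], fields[6]
    name = f"{sample}#{hap}#{seqid}"
    steps = [
        (nid, "+" if sign == ">" else "-") for sign, nid in _WALK_STEP_RE.findall(walk)
    ]
    if not steps:
        raise GFAParseError(f"line {lineno}: empty walk for {name}")
    return PathRecord(name, steps)


def parse_gfa(source: IO[str] | Iterable[str]) -> VariationGraph:
    """Parse a GFAv1 text stream into a validated :class:`VariationGraph`.

    Lines are processed one at a time, so memory scales with graph size rather
    than file size.  Duplicate canonical links are silently deduplicated;
    links with overlaps other than ``*``/``0M`` trigger a one-time warning that
    bp statistics treat the graph as blunt-ended.
    """
    graph = VariationGraph()
    seen_links: set[tuple[str, str, str, str]] = set()
    warned_overlap = False
    warned_types: set[str] = set()
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        rec = fields[0]
        if rec == "H":
            continue
        if rec == "S":
            seg = _parse_segment(fields, lineno)
            if seg.id in graph.segments:
                raise GFAValidationError(f"line {lineno}: duplicate segment id {seg.id}")
            graph.segments[seg.id] = seg
        elif rec == "L":
            link = _parse_link(fields, lineno)
            if link.overlap not in ("*", "0M") and not warned_overlap:
                logger.warning(
                    "non-blunt overlap %r on a link: bp statistics treat the "
                    "graph as blunt-ended (no overlap subtraction)",
                    link.overlap,
                )
                warned_overlap = True
            if link.key not in seen_links:
                seen_links.add(link.key)
                graph.links.append(link)
        elif rec == "P":
            graph.paths.append(_parse_path(fields, lineno))
        elif rec == "W":
            graph.paths.append(_parse_walk(fields, lineno))
        else:
            if rec not in warned_types:
                logger.warning("skipping unsupported GFA record type %r", rec)
                warned_types.add(rec)
    graph.validate()
    return graph


def parse_gfa_text(text: str) -> VariationGraph:
    """Parse a GFAv1 document given as a single string."""
    return parse_gfa(text.splitlines())


def parse_gfa_file(path) -> VariationGraph:
    with open(path, encoding="utf-8") as handle:
        return parse_gfa(handle)


# ---------------------------------------------------------------------------
# writing


def write_gfa(graph: VariationGraph, sink: IO[str]) -> None:
    """Emit H, then S (ascending id), then canonical sorted L, then P lines."""
    sink.write("H\tVN:Z:1.0\n")
    for nid in sorted(graph.segments, key=_id_sort_key):
        seg = graph.segments[nid]
        if seg.sequence is None:
            sink.write(f"S\t{nid}\t*\tLN:i:{seg.length}\n")
        else:
            sink.write(f"S\t{nid}\t{seg.sequence}\n")
    for link in sorted(graph.links, key=lambda l: _link_order_key(*l.key)):
        sink.write(
            f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}\t"
            f"{link.to_orient}\t{link.overlap}\n"
        )
    for path in graph.paths:
        steps = ",".join(f"{nid}{orient}" for nid, orient in path.steps)
        sink.write(f"P\t{path.name}\t{steps}\t*\n")


def write_gfa_text(graph: VariationGraph) -> str:
    import io

    buf = io.StringIO()
    write_gfa(graph, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# node id normalization


def node2int(graph: VariationGraph) -> tuple[VariationGraph, dict[str, str]]:
    """Relabel segments with consecutive numeric ids 1..N.

    New ids follow the order of first appearance as S records.  Links are
    re-canonicalized under the new labels (relabeling can change which side of
    a bidirected edge is the canonical one) and path steps are rewritten.
    Returns the relabeled graph and the old-id -> new-id mapping.
    """
    mapping = {old: str(i) for i, old in enumerate(graph.segments, start=1)}
    segments = {
        mapping[old]: Segment(mapping[old], seg.sequence, seg.length)
        for old, seg in graph.segments.items()
    }
    links: list[Link] = []
    seen: set[tuple[str, str, str, str]] = set()
    for l in graph.links:
        new = canonicalize_link(
            mapping[l.from_id], l.from_orient, mapping[l.to_id], l.to_orient, l.overlap
        )
        if new.key not in seen:
            seen.add(new.key)
            links.append(new)
    paths = [
        PathRecord(p.name, [(mapping[nid], orient) for nid, orient in p.steps])
        for p in graph.paths
    ]
    return VariationGraph(segments, links, paths), mapping


def write_id_map(mapping: dict[str, str], sink: IO[str]) -> None:
    """Write an id mapping as 2-column TSV with header."""
    sink.write("old_id\tnew_id\n")
    for old, new in mapping.items():
        sink.write(f"{old}\t{new}\n")
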
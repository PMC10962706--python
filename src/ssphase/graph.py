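"""Assembly graph model: GFA1 I/O, rDNA-tangle excision, components, length filter.

The assembly graph is the unitig graph emitted by a long-read assembler
(e.g. a Verkko or hifiasm homopolymer-compressed unitig graph). Only the
topology and unitig lengths matter here; sequences are never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Unitig",
    "Link",
    "AssemblyGraph",
    "GFAParseError",
    "read_gfa",
    "write_gfa",
    "excise_rdna_tangle",
    "component_labels",
    "filter_by_length",
]

DEFAULT_MIN_UNITIG_LEN = 50_000
DEFAULT_RDNA_SHORT_LEN = 50_000


class GFAParseError(ValueError):
    """Raised for malformed or inconsistent GFA1 input."""


@dataclass(frozen=True)
class Unitig:
    """A node of the assembly graph.

    Parameters
    ----------
    id : str
        Segment name, unique within a graph.
    length : int
        Length in bp (> 0), from the sequence or the ``LN:i`` tag.
    coverage : float
        Mean alignment depth (``rd:f``) or read count (``RC:i``) if present;
        0.0 otherwise. Used only to rank unitigs for clustering batches.
    """

    id: str
    length: int
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"unitig {self.id!r}: length must be positive, got {self.length}")


@dataclass(frozen=True)
class Link:
    """An undirected graph edge with GFA end orientations."""

    from_id: str
    to_id: str
    from_end: str = "+"
    to_end: str = "+"


@dataclass
class AssemblyGraph:
    """Unitigs plus links, with lazily computed connected-component labels."""

    unitigs: dict[str, Unitig] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.unitigs)

    def add_unitig(self, unitig: Unitig) -> None:
        if unitig.id in self.unitigs:
            raise GFAParseError(f"duplicate segment id {unitig.id!r}")
        self.unitigs[unitig.id] = unitig

    def add_link(self, link: Link) -> None:
        for uid in (link.from_id, link.to_id):
            if uid not in self.unitigs:
                raise GFAParseError(f"link references unknown segment {uid!r}")
        self.links.append(link)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.unitigs)
        g.add_edges_from((l.from_id, l.to_id) for l in self.links)
        return g

    def remove_unitigs(self, ids: set[str]) -> "AssemblyGraph":
        """Return a copy with ``ids`` and all incident links removed."""
        kept = {uid: u for uid, u in self.unitigs.items() if uid not in ids}
        links = [l for l in self.links if l.from_id not in ids and l.to_id not in ids]
        return AssemblyGraph(unitigs=kept, links=links)

    @property
    def lengths(self) -> dict[str, int]:
        return {uid: u.length for uid, u in self.unitigs.items()}


_COV_TAGS = (re.compile(r"^rd:f:([-+0-9.eE]+)$"), re.compile(r"^RC:i:(\d+)$"))
_LN_TAG = re.compile(r"^LN:i:(\d+)$")


def read_gfa(path) -> AssemblyGraph:
    """Read a GFA1 file into an :class:`AssemblyGraph`.

    S-lines must carry a sequence or a ``*`` placeholder with an ``LN:i`` tag.
    Coverage is taken from ``rd:f`` or ``RC:i`` tags when present. Lines other
    than S and L (headers, paths, ...) are ignored.
    """
    graph = AssemblyGraph()
    pending_links: list[tuple[int, Link]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            rtype = fields[0]
            if rtype == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S-line needs name and sequence")
                name, seq = fields[1], fields[2]
                tags = fields[3:]
                length = None
                coverage = 0.0
                if seq != "*":
                    length = len(seq)
                for tag in tags:
                    m = _LN_TAG.match(tag)
                    if m:
                        length = int(m.group(1))
                    for pat in _COV_TAGS:
                        m = pat.match(tag)
                        if m:
                            coverage = float(m.group(1))
                if length is None:
                    raise GFAParseError(
                        f"line {lineno}: segment {name!r} has no sequence and no LN:i tag"
                    )
                graph.add_unitig(Unitig(id=name, length=length, coverage=coverage))
            elif rtype == "L":
                if len(fields) < 5:
                    raise GFAParseError(f"line {lineno}: L-line needs 4 fields after 'L'")
                pending_links.append(
                    (lineno, Link(fields[1], fields[3], fields[2], fields[4]))
                )
    for lineno, link in pending_links:
        try:
            graph.add_link(link)
        except GFAParseError as exc:
            raise GFAParseError(f"line {lineno}: {exc}") from None
    return graph


def write_gfa(graph: AssemblyGraph, path) -> None:
    """Write S/L lines (``*`` sequence + LN/rd tags); inverse of :func:`read_gfa`."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for u in graph.unitigs.values():
            fh.write(f"S\t{u.id}\t*\tLN:i:{u.length}\trd:f:{u.coverage:g}\n")
        for l in graph.links:
            fh.write(f"L\t{l.from_id}\t{l.from_end}\t{l.to_id}\t{l.to_end}\t0M\n")


def excise_rdna_tangle(
    graph: AssemblyGraph, short_len: int = DEFAULT_RDNA_SHORT_LEN
) -> tuple[AssemblyGraph, set[str]]:
    """Remove the putative rDNA tangle from the graph.

    The acrocentric chromosomes are joined by near-identical rDNA arrays into
    one densely connected component of short nodes, defeating the
    connected-component clustering heuristic. The component with the largest
    summed bp is taken as the putative acrocentric component; within it, the
    connected subgraph induced by nodes strictly shorter than ``short_len``
    (default 50 kbp) with the largest summed bp (ties: more nodes, then
    smallest member id) is excised together with all incident links.

    Returns the pruned graph and the set of removed unitig ids.
    """
    if not graph.unitigs:
        return graph, set()
    g = graph.to_networkx()
    components = list(nx.connected_components(g))
    bp = graph.lengths
    largest = sorted(components, key=lambda comp: (-sum(bp[u] for u in comp), min(comp)))[0]
    short = {u for u in largest if bp[u] < short_len}
    if not short:
        return graph, set()
    sub = g.subgraph(short)
    tangles = list(nx.connected_components(sub))
    # largest summed bp; ties broken by node count, then by smallest member id
    tangle = sorted(
        tangles, key=lambda t: (-sum(bp[u] for u in t), -len(t), min(t))
    )[0]
    removed = set(tangle)
    return graph.remove_unitigs(removed), removed


def component_labels(graph: AssemblyGraph) -> dict[str, int]:
    """Label connected components, ignoring link orientations.

    Components are numbered 0, 1, ... in order of their smallest member id,
    so labels are deterministic for a given graph.
    """
    g = graph.to_networkx()
    comps = sorted(nx.connected_components(g), key=min)
    return {uid: i for i, comp in enumerate(comps) for uid in comp}


def filter_by_length(graph: AssemblyGraph, min_len: int = DEFAULT_MIN_UNITIG_LEN) -> set[str]:
    """Ids of unitigs long enough to enter clustering (length >= ``min_len``).

    Short unitigs carry too few Strand-seq alignments for a reliable strand
    state; they stay in the graph for reporting but are excluded downstream.
    """
    return {uid for uid, u in graph.unitigs.items() if u.length >= min_len}
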
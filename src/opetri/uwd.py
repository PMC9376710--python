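"""Undirected wiring diagrams: the syntax of composition.

A UWD has boxes (slots for subsystems), ports (attachment points, each
assigned to a box and wired to a junction) and junctions (shared variables).
An optional ordered table of outer ports exposes junctions as the interface
of the composite; a diagram with no outer ports describes a closed system.

Diagrams compose hierarchically: `uwd_substitute` replaces a box with an
entire inner diagram, merging the inner diagram's interface junctions with
the junctions the box's ports were wired to.  This substitution is the
operadic composition of the syntax and is associative up to isomorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Port",
    "UWD",
    "validate_uwd",
    "uwd_summary",
    "uwd_substitute",
    "uwd_isomorphic",
]


@dataclass(frozen=True)
class Port:
    box: int
    junction: int


@dataclass
class UWD:
    """An undirected wiring diagram as four ordered tables (0-based indices)."""

    boxes: list[str] = field(default_factory=list)
    ports: list[Port] = field(default_factory=list)
    junctions: list[str] = field(default_factory=list)
    outer_ports: list[int] = field(default_factory=list)  # junction indices

    def box_ports(self, b: int) -> list[int]:
        """Global port indices assigned to box ``b``, in port-table order."""
        return [i for i, p in enumerate(self.ports) if p.box == b]


def validate_uwd(d: UWD) -> list[str]:
    """Violation descriptions (empty if valid).  An isolated junction — one
    wired to no port — is legal and reported as a ``warning:`` entry."""
    out: list[str] = []
    for i, p in enumerate(d.ports):
        if not 0 <= p.box < len(d.boxes):
            out.append(f"ports row {i}: box index {p.box} out of range")
        if not 0 <= p.junction < len(d.junctions):
            out.append(f"ports row {i}: junction index {p.junction} out of range")
    for i, j in enumerate(d.outer_ports):
        if not 0 <= j < len(d.junctions):
            out.append(f"outer_ports row {i}: junction index {j} out of range")
    if not out:
        used = {p.junction for p in d.ports} | set(d.outer_ports)
        for j in range(len(d.junctions)):
            if j not in used:
                out.append(f"warning: junctions row {j} is wired to no port")
    return out


def uwd_violations(d: UWD) -> list[str]:
    """Hard violations only (warnings stripped)."""
    return [v for v in validate_uwd(d) if not v.startswith("warning:")]


def uwd_summary(d: UWD) -> tuple[int, int, int]:
    """(box count, port count, junction count)."""
    return len(d.boxes), len(d.ports), len(d.junctions)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, x, y) -> None:
        self.parent[self.find(x)] = self.find(y)


def uwd_substitute(
    outer: UWD,
    box: int,
    inner: UWD,
    port_correspondence: list[int] | None = None,
) -> UWD:
    """Replace ``box`` of ``outer`` by the diagram ``inner`` and flatten.

    ``port_correspondence[k]`` is the global outer-port index (a port of
    ``box``) matched with outer port ``k`` of ``inner``; by default they are
    matched in order.  The junction each matched pair exposes/wires is
    merged.  Result ordering: surviving outer rows first (original order),
    then inner rows not merged away.
    """
    if not 0 <= box < len(outer.boxes):
        raise IndexError(f"box index {box} out of range")
    bports = outer.box_ports(box)
    if len(inner.outer_ports) != len(bports):
        raise ValueError(
            f"inner diagram exposes {len(inner.outer_ports)} ports but box "
            f"{box} has {len(bports)} ports"
        )
    corr = list(bports) if port_correspondence is None else list(port_correspondence)
    if sorted(corr) != sorted(bports):
        raise ValueError("port_correspondence is not a bijection onto the box's ports")

    uf = _UnionFind()
    for k, outer_port in enumerate(corr):
        uf.union(("i", inner.outer_ports[k]), ("o", outer.ports[outer_port].junction))

    # junction classes: outer junctions first (a class may contain several
    # outer junctions if the inner wiring merges them), then unmerged inner
    new_j_index: dict = {}
    labels: list[str] = []
    for j in range(len(outer.junctions)):
        root = uf.find(("o", j))
        if root in new_j_index:
            new_j_index[("o", j)] = new_j_index[root]
        else:
            new_j_index[root] = new_j_index[("o", j)] = len(labels)
            labels.append(outer.junctions[j])
    for j in range(len(inner.junctions)):
        root = uf.find(("i", j))
        if root in new_j_index:
            new_j_index[("i", j)] = new_j_index[root]
        else:
            new_j_index[root] = new_j_index[("i", j)] = len(labels)
            labels.append(inner.junctions[j])

    boxes = [lbl for b, lbl in enumerate(outer.boxes) if b != box] + list(inner.boxes)
    outer_box_renum = {}
    k = 0
    for b in range(len(outer.boxes)):
        if b != box:
            outer_box_renum[b] = k
            k += 1
    inner_box_offset = k

    ports: list[Port] = []
    for p in outer.ports:
        if p.box == box:
            continue
        ports.append(Port(outer_box_renum[p.box], new_j_index[("o", p.junction)]))
    for p in inner.ports:
        ports.append(Port(inner_box_offset + p.box, new_j_index[("i", p.junction)]))

    outer_ports = [new_j_index[("o", j)] for j in outer.outer_ports]
    return UWD(boxes=boxes, ports=ports, junctions=labels, outer_ports=outer_ports)


def _uwd_graph(d: UWD):
    import networkx as nx
    from collections import Counter

    g = nx.Graph()
    for i in range(len(d.boxes)):
        g.add_node(("b", i), kind="box")
    for j in range(len(d.junctions)):
        g.add_node(("j", j), kind="junction")
    for (b, j), m in Counter((p.box, p.junction) for p in d.ports).items():
        g.add_edge(("b", b), ("j", j), m=m)
    # outer ports are ordered: pin each position with its own node colour
    for k, j in enumerate(d.outer_ports):
        g.add_node(("o", k), kind=f"outer{k}")
        g.add_edge(("o", k), ("j", j), m=1)
    return g


def uwd_isomorphic(a: UWD, b: UWD) -> bool:
    """Isomorphism of UWDs: bijections of boxes and junctions under which the
    port multisets and the ordered outer-port sequences agree; labels are
    ignored.  Decided by VF2 on a coloured multigraph encoding."""
    import networkx as nx

    if (
        len(a.boxes) != len(b.boxes)
        or len(a.ports) != len(b.ports)
        or len(a.junctions) != len(b.junctions)
        or len(a.outer_ports) != len(b.outer_ports)
    ):
        return False
    return nx.is_isomorphic(
        _uwd_graph(a),
        _uwd_graph(b),
        node_match=lambda x, y: x["kind"] == y["kind"],
        edge_match=lambda x, y: x["m"] == y["m"],
    )
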
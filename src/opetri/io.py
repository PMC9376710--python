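"""JSON serialization (schemas petri-v1, open-petri-v1, uwd-v1,
typed-petri-v1, all 0-based) and DOT export.

Documents are validated structurally on load; errors name the path into
the document (e.g. ``input_arcs[3].species``)."""

from __future__ import annotations

import json
from pathlib import Path

from .open_net import OpenPetriNet
from .petri import Arc, PetriMorphism, PetriNet, Transition
from .typed import TypedPetriNet
from .uwd import UWD, Port

__all__ = [
    "save_model",
    "load_model",
    "petri_to_dict",
    "petri_from_dict",
    "model_to_dict",
    "model_from_dict",
    "petri_to_dot",
    "uwd_to_dot",
]


class SchemaError(ValueError):
    """A document does not conform to its schema; the message names the path."""


def _need(doc: dict, key: str, typ, path: str):
    if not isinstance(doc, dict) or key not in doc:
        raise SchemaError(f"{path or 'document'}: missing required key {key!r}")
    v = doc[key]
    if not isinstance(v, typ):
        raise SchemaError(f"{path}.{key}: expected {typ.__name__}, got {type(v).__name__}")
    return v


def petri_to_dict(net: PetriNet) -> dict:
    return {
        "schema": "petri-v1",
        "species": [{"label": s} for s in net.species],
        "transitions": [
            {"label": t.label, **({"rate": t.rate} if t.rate is not None else {})}
            for t in net.transitions
        ],
        "input_arcs": [{"species": a.species, "transition": a.transition} for a in net.input_arcs],
        "output_arcs": [{"species": a.species, "transition": a.transition} for a in net.output_arcs],
    }


def petri_from_dict(doc: dict, path: str = "") -> PetriNet:
    species = [
        _need(row, "label", str, f"{path}species[{i}]")
        for i, row in enumerate(_need(doc, "species", list, path.rstrip(".")))
    ]
    transitions = []
    for i, row in enumerate(_need(doc, "transitions", list, path.rstrip("."))):
        label = _need(row, "label", str, f"{path}transitions[{i}]")
        rate = row.get("rate")
        if rate is not None and not isinstance(rate, (int, float)):
            raise SchemaError(f"{path}transitions[{i}].rate: expected number")
        transitions.append(Transition(label, rate))

    def arcs(key: str) -> list[Arc]:
        out = []
        for i, row in enumerate(_need(doc, key, list, path.rstrip("."))):
            s = _need(row, "species", int, f"{path}{key}[{i}]")
            t = _need(row, "transition", int, f"{path}{key}[{i}]")
            out.append(Arc(s, t))
        return out

    return PetriNet(species, transitions, arcs("input_arcs"), arcs("output_arcs"))


def _morphism_to_dict(f: PetriMorphism) -> dict:
    return {
        "species_map": list(f.species_map),
        "transition_map": list(f.transition_map),
        "input_arc_map": list(f.input_arc_map),
        "output_arc_map": list(f.output_arc_map),
    }


def _morphism_from_dict(doc: dict, path: str) -> PetriMorphism:
    maps = []
    for key in ("species_map", "transition_map", "input_arc_map", "output_arc_map"):
        m = _need(doc, key, list, path)
        if not all(isinstance(x, int) for x in m):
            raise SchemaError(f"{path}.{key}: expected a list of integers")
        maps.append(tuple(m))
    return PetriMorphism(*maps)


def model_to_dict(obj) -> dict:
    """Serialize a PetriNet, OpenPetriNet, UWD or TypedPetriNet."""
    if isinstance(obj, PetriNet):
        return petri_to_dict(obj)
    if isinstance(obj, OpenPetriNet):
        doc = petri_to_dict(obj.net)
        doc["schema"] = "open-petri-v1"
        doc["feet"] = [list(leg) for leg in obj.legs]
        return doc
    if isinstance(obj, UWD):
        return {
            "schema": "uwd-v1",
            "boxes": [{"label": b} for b in obj.boxes],
            "ports": [{"box": p.box, "junction": p.junction} for p in obj.ports],
            "junctions": [{"label": j} for j in obj.junctions],
            "outer_ports": [{"junction": j} for j in obj.outer_ports],
        }
    if isinstance(obj, TypedPetriNet):
        return {
            "schema": "typed-petri-v1",
            "net": petri_to_dict(obj.net),
            "type_net": petri_to_dict(obj.type_net),
            "typing": _morphism_to_dict(obj.typing),
        }
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def model_from_dict(doc: dict):
    schema = _need(doc, "schema", str, "")
    if schema == "petri-v1":
        return petri_from_dict(doc)
    if schema == "open-petri-v1":
        net = petri_from_dict(doc)
        legs = _need(doc, "feet", list, "")
        for k, leg in enumerate(legs):
            if not isinstance(leg, list) or not all(isinstance(s, int) for s in leg):
                raise SchemaError(f"feet[{k}]: expected a list of species indices")
        return OpenPetriNet(net=net, feet=[len(l) for l in legs], legs=[list(l) for l in legs])
    if schema == "uwd-v1":
        boxes = [
            _need(row, "label", str, f"boxes[{i}]")
            for i, row in enumerate(_need(doc, "boxes", list, ""))
        ]
        ports = [
            Port(_need(row, "box", int, f"ports[{i}]"), _need(row, "junction", int, f"ports[{i}]"))
            for i, row in enumerate(_need(doc, "ports", list, ""))
        ]
        junctions = [
            _need(row, "label", str, f"junctions[{i}]")
            for i, row in enumerate(_need(doc, "junctions", list, ""))
        ]
        outer = [
            _need(row, "junction", int, f"outer_ports[{i}]")
            for i, row in enumerate(doc.get("outer_ports", []))
        ]
        return UWD(boxes, ports, junctions, outer)
    if schema == "typed-petri-v1":
        return TypedPetriNet(
            net=petri_from_dict(_need(doc, "net", dict, ""), "net."),
            type_net=petri_from_dict(_need(doc, "type_net", dict, ""), "type_net."),
            typing=_morphism_from_dict(_need(doc, "typing", dict, ""), "typing"),
        )
    raise SchemaError(f"unknown schema {schema!r}")


def save_model(obj, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(obj), indent=2) + "\n")


def load_model(path):
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# DOT export


def petri_to_dot(net: PetriNet, heat: dict[str, float] | None = None) -> str:
    """DOT text: species as circles, transitions as squares, arc
    multiplicities as edge labels.  ``heat`` optionally colours transitions
    by a signed value (red positive, blue negative, scaled to the largest
    magnitude)."""
    from collections import Counter

    lines = ["digraph petri {", "  rankdir=LR;"]
    for i, s in enumerate(net.species):
        lines.append(f'  s{i} [label="{s}", shape=circle];')
    hmax = max((abs(v) for v in (heat or {}).values()), default=0.0)
    for j, t in enumerate(net.transitions):
        style = ""
        if heat is not None and t.label in heat and hmax > 0:
            v = heat[t.label] / hmax
            # interpolate white -> red for positive, white -> blue for negative
            if v >= 0:
                col = f'"#ff{int(255 * (1 - v)):02x}{int(255 * (1 - v)):02x}"'
            else:
                col = f'"#{int(255 * (1 + v)):02x}{int(255 * (1 + v)):02x}ff"'
            style = f", style=filled, fillcolor={col}"
        lines.append(f'  t{j} [label="{t.label}", shape=square{style}];')
    inputs = Counter((a.species, a.transition) for a in net.input_arcs)
    outputs = Counter((a.species, a.transition) for a in net.output_arcs)
    for (s, t), m in sorted(inputs.items()):
        lbl = f' [label="{m}"]' if m > 1 else ""
        lines.append(f"  s{s} -> t{t}{lbl};")
    for (s, t), m in sorted(outputs.items()):
        lbl = f' [label="{m}"]' if m > 1 else ""
        lines.append(f"  t{t} -> s{s}{lbl};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def uwd_to_dot(d: UWD) -> str:
    """DOT text: boxes as rounded rectangles, junctions as dots, wires as
    undirected edges."""
    lines = ["graph uwd {", "  layout=neato;"]
    for i, b in enumerate(d.boxes):
        lines.append(f'  b{i} [label="{b}", shape=box, style=rounded];')
    for j, lbl in enumerate(d.junctions):
        lines.append(f'  j{j} [label="{lbl}", shape=point, xlabel="{lbl}"];')
    for p in d.ports:
        lines.append(f"  b{p.box} -- j{p.junction};")
    for k, j in enumerate(d.outer_ports):
        lines.append(f'  o{k} [label="", shape=none];')
        lines.append(f"  o{k} -- j{j} [style=dashed];")
    lines.append("}")
    return "\n".join(lines) + "\n"
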
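"""State→rate→state dependency graphs, state classification, causal diagrams.

The dependency graph is bipartite by construction: a state points at every
rate whose expression contains it, and a rate points at every state with a
structurally non-zero stoichiometric entry.  Classification follows the graph
alone: states with at least one child (a rate they influence) form the
dynamic core; states that are only written to are measurement-only; isolated
states are uncoupled.

A feature's causal diagram has the feature as the single child and the states
occurring in its symbolic conditions as parents.  Two parents are adjacent if
one influences the other through a single rate hop.  Non-adjacent parent
pairs are immoralities (V-structures): conditioning on the feature associates
them, which is how false-positive detections arise.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import sympy as sp

from .model import GujerModel
from .symbolic import FeatureSpec, condition_states, ramp_conditions, extremum_conditions

__all__ = [
    "dependency_graph",
    "classify_states",
    "feature_causal_diagram",
    "immoralities",
    "write_dot",
    "write_graphml",
    "write_edge_csv",
]


def _structurally_nonzero(entry: sp.Expr) -> bool:
    return sp.simplify(sp.sympify(entry)) != 0


def dependency_graph(model: GujerModel) -> nx.DiGraph:
    """Directed bipartite graph with ``kind`` = ``"state"`` | ``"rate"`` nodes.

    Edge ``state → rate`` iff the state occurs in the rate expression; edge
    ``rate → state`` iff the stoichiometric entry is structurally non-zero
    (decided symbolically, so zero-valued parameters do not delete edges).
    Actuated states carry an ``actuated=True`` attribute.
    """
    g = nx.DiGraph(model=model.name)
    for sv in model.states:
        g.add_node(
            sv.name, kind="state", unit=sv.unit, actuated=sv.name in model.actuation
        )
    for j, (pname, rate) in enumerate(zip(model.process_names, model.rates)):
        g.add_node(pname, kind="rate")
        free = sp.sympify(rate).free_symbols
        for sv in model.states:
            if model.states.symbol(sv.name) in free:
                g.add_edge(sv.name, pname)
            if _structurally_nonzero(model.stoichiometry[model.states.index(sv.name), j]):
                g.add_edge(pname, sv.name)
    return g


def classify_states(graph: nx.DiGraph) -> dict[str, tuple[str, ...]]:
    """Partition state nodes into dynamic core / uncoupled / measurement-only.

    ``dynamic_core``: at least one child (the state drives some rate);
    ``measurement_only``: parents but no children; ``uncoupled``: neither.
    Output order follows node insertion order (= model state order), so the
    partition is stable under relabelling but reflects the model.
    """
    dynamic, uncoupled, measurement = [], [], []
    for node, data in graph.nodes(data=True):
        if data.get("kind") != "state":
            continue
        has_child = graph.out_degree(node) > 0
        has_parent = graph.in_degree(node) > 0
        if has_child:
            dynamic.append(node)
        elif has_parent:
            measurement.append(node)
        else:
            uncoupled.append(node)
    return {
        "dynamic_core": tuple(dynamic),
        "uncoupled": tuple(uncoupled),
        "measurement_only": tuple(measurement),
    }


def _state_adjacent(graph: nx.DiGraph, a: str, b: str) -> bool:
    """One-rate-hop influence in either direction: A→rate→B or B→rate→A."""
    for mid in graph.successors(a):
        if graph.has_edge(mid, b):
            return True
    for mid in graph.successors(b):
        if graph.has_edge(mid, a):
            return True
    return False


def feature_causal_diagram(model: GujerModel, feature: FeatureSpec) -> nx.DiGraph:
    """Causal diagram of a feature: parents → feature child node.

    Parents are exactly the states occurring in the feature's symbolic
    conditions.  Parent–parent edges copy one-rate-hop adjacency from the
    dependency graph (both directions preserved).
    """
    if feature.kind == "ramp":
        conds = ramp_conditions(model, feature.signal)
    else:
        conds = extremum_conditions(model, feature.signal, feature.kind)
    parents = condition_states(conds)
    dep = dependency_graph(model)
    child = f"{feature.signal}_{feature.kind}"
    g = nx.DiGraph(model=model.name, signal=feature.signal, kind=feature.kind)
    g.add_node(child, kind="feature")
    for p in parents:
        g.add_node(p, kind="state")
        g.add_edge(p, child)
    for i, a in enumerate(parents):
        for b in parents[i + 1 :]:
            for mid in dep.successors(a):
                if dep.has_edge(mid, b):
                    g.add_edge(a, b)
                    break
            for mid in dep.successors(b):
                if dep.has_edge(mid, a):
                    g.add_edge(b, a)
                    break
    return g


def immoralities(diagram: nx.DiGraph) -> list[tuple[str, str]]:
    """Unordered non-adjacent parent pairs sharing the feature child.

    Returned in lexicographic order; symmetric in pair order by construction.
    """
    children = [n for n, d in diagram.nodes(data=True) if d.get("kind") == "feature"]
    if len(children) != 1:
        raise ValueError("diagram must have exactly one feature node")
    child = children[0]
    parents = sorted(p for p in diagram.predecessors(child))
    out = []
    for i, a in enumerate(parents):
        for b in parents[i + 1 :]:
            if not (diagram.has_edge(a, b) or diagram.has_edge(b, a)):
                out.append((a, b))
    return out


# -- export ----------------------------------------------------------------

_DOT_STYLE = {
    "state": 'shape=ellipse, width=1.0',
    "rate": 'shape=circle, width=0.4, fontsize=9',
    "feature": 'shape=doublecircle',
}
_CLASS_COLOR = {
    "dynamic_core": "lightcoral",
    "measurement_only": "pink",
    "uncoupled": "grey",
}


def write_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Minimal DOT writer (node class colouring mirrors the classification)."""
    classes = {}
    if any(d.get("kind") == "state" for _, d in graph.nodes(data=True)):
        try:
            part = classify_states(graph)
            classes = {n: c for c, ns in part.items() for n in ns}
        except Exception:  # feature diagrams have no rate nodes
            classes = {}
    lines = ["digraph dependency {"]
    for node, data in graph.nodes(data=True):
        kind = data.get("kind", "state")
        style = _DOT_STYLE.get(kind, "")
        color = _CLASS_COLOR.get(classes.get(node, ""), "white")
        lines.append(
            f'  "{node}" [{style}, style=filled, fillcolor={color}, '
            f'label="{node}"];'
        )
    for a, b in graph.edges():
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_edge_csv(graph: nx.DiGraph, path: str | Path) -> None:
    """Edge list ``source,target,kind`` where kind is ``<src kind>-><dst kind>``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "kind"])
        for a, b in graph.edges():
            kind = f"{graph.nodes[a].get('kind', '?')}->{graph.nodes[b].get('kind', '?')}"
            writer.writerow([a, b, kind])
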
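"""Weighted directed signaling networks.

A :class:`SignalingNetwork` is a directed acyclic collection of protein
nodes and weighted activating edges.  Edge weights are dimensionless
interaction strengths in [0, 1]; a weight of ``None`` means "not yet
assigned" (to be sampled or set explicitly before simulation).

Node roles follow the topology: a *receptor* has no incoming edges (it is
activated only by external stimuli), a *terminal* has no outgoing edges
(it represents a readout such as a cell phenotype), everything else is
*internal*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProteinNode",
    "WeightedEdge",
    "SignalingNetwork",
    "NetworkValidationError",
    "NetworkParseError",
    "load_network",
    "write_network",
    "build_mapk_fixture",
    "sample_weights",
    "set_uniform_weights",
]

ROLES = ("receptor", "internal", "terminal")

#: SIF relation token; only positive (activating) interactions exist.
SIF_RELATION = "act"


class NetworkValidationError(ValueError):
    """A structurally invalid network (dangling edge, bad weight, ...)."""


class NetworkParseError(ValueError):
    """A malformed network file."""


@dataclass(frozen=True)
class ProteinNode:
    """A protein in the pathway.

    Parameters
    ----------
    id:
        Short unique identifier (e.g. ``"EGFR"``).
    name:
        Display name; defaults to ``id``.
    role:
        One of ``"receptor"``, ``"internal"``, ``"terminal"``, or ``None``
        to infer the role from topology at validation time.
    """

    id: str
    name: str | None = None
    role: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be non-empty")
        if self.role is not None and self.role not in ROLES:
            raise NetworkValidationError(
                f"node {self.id!r}: unknown role {self.role!r}"
            )

    @property
    def display_name(self) -> str:
        return self.name if self.name is not None else self.id


@dataclass(frozen=True)
class WeightedEdge:
    """A directed activating interaction ``source -> target``.

    ``weight`` is the interaction strength in [0, 1], or ``None`` when
    unset.  Weights are constant over a simulation.
    """

    source: str
    target: str
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.weight is not None and not (0.0 <= self.weight <= 1.0):
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: weight {self.weight} "
                "outside [0, 1]"
            )


@dataclass
class SignalingNetwork:
    """A validated weighted directed signaling network.

    Nodes and edges keep their declaration order; the per-node outgoing
    edge lists (used by the Boolean gates) are ordered the same way.
    """

    nodes: list[ProteinNode]
    edges: list[WeightedEdge]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate node id(s): {dup}")
        known = set(ids)
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target} references undeclared "
                        f"node {endpoint!r}"
                    )
            if e.source == e.target:
                raise NetworkValidationError(
                    f"self-loop on node {e.source!r} is not allowed"
                )
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise NetworkValidationError(
                    f"duplicate edge {e.source}->{e.target}"
                )
            seen_pairs.add(pair)
        # roles must match topology where declared
        for node in self.nodes:
            inferred = self._infer_role(node.id)
            if node.role is not None and node.role != inferred:
                raise NetworkValidationError(
                    f"node {node.id!r}: declared role {node.role!r} "
                    f"contradicts topology (inferred {inferred!r})"
                )

    def _infer_role(self, node_id: str) -> str:
        has_in = any(e.target == node_id for e in self.edges)
        has_out = any(e.source == node_id for e in self.edges)
        if not has_in:
            return "receptor"
        if not has_out:
            return "terminal"
        return "internal"

    # -- accessors ----------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node_index(self, node_id: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.id == node_id:
                return i
        raise KeyError(f"unknown node {node_id!r}")

    def role(self, node_id: str) -> str:
        node = self.nodes[self.node_index(node_id)]
        return node.role if node.role is not None else self._infer_role(node.id)

    @property
    def receptors(self) -> list[str]:
        return [n.id for n in self.nodes if self.role(n.id) == "receptor"]

    @property
    def terminals(self) -> list[str]:
        return [n.id for n in self.nodes if self.role(n.id) == "terminal"]

    def out_edges(self, node_id: str) -> list[WeightedEdge]:
        self.node_index(node_id)  # raise KeyError for unknown nodes
        return [e for e in self.edges if e.source == node_id]

    def in_nodes(self, node_id: str) -> list[str]:
        self.node_index(node_id)
        return [e.source for e in self.edges if e.target == node_id]

    def outgoing_weights(self, node_id: str) -> list[float]:
        """Ordered outgoing weights of ``node_id`` (raises if any unset)."""
        weights = []
        for e in self.out_edges(node_id):
            if e.weight is None:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target} has no weight set"
                )
            weights.append(e.weight)
        return weights

    def has_unset_weights(self) -> bool:
        return any(e.weight is None for e in self.edges)

    def edge_weight(self, source: str, target: str) -> float | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.weight
        raise KeyError(f"unknown edge {source}->{target}")

    def adjacency_matrix(self) -> np.ndarray:
        """Binary adjacency A with A[k, i] = 1 iff edge k -> i."""
        n = len(self.nodes)
        idx = {node_id: i for i, node_id in enumerate(self.node_ids)}
        a = np.zeros((n, n))
        for e in self.edges:
            a[idx[e.source], idx[e.target]] = 1.0
        return a

    def with_weights(self, weights: Sequence[float]) -> "SignalingNetwork":
        """Copy of the network with edge weights replaced in edge order."""
        if len(weights) != len(self.edges):
            raise ValueError(
                f"expected {len(self.edges)} weights, got {len(weights)}"
            )
        new_edges = [
            replace(e, weight=float(w)) for e, w in zip(self.edges, weights)
        ]
        return SignalingNetwork(list(self.nodes), new_edges)

    def to_networkx(self):
        """The topology as a :class:`networkx.DiGraph` (weights as attrs)."""
        import networkx as nx

        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node.id, name=node.display_name, role=self.role(node.id))
        for e in self.edges:
            g.add_edge(e.source, e.target, weight=e.weight)
        return g


# -- fixture -----------------------------------------------------------


def build_mapk_fixture() -> SignalingNetwork:
    """The simplified MAPK cascade used throughout: 11 proteins, 14 edges.

    Three receptors (EGFR, ERBB2, MET) converge on the adaptor GRB2, which
    feeds the backbone GRB2 -> SOS -> RAS -> RAF -> MEK -> ERK -> Phenotype.
    Each receptor carries exactly two outgoing interactions: one to GRB2
    and one to ``AUX``, an auxiliary adaptor layer (SHC/GAB-like) that
    re-injects receptor signal into the backbone at SOS and RAS.  GRB2
    carries exactly one outgoing interaction (to SOS).  ``Phenotype``
    stands for an ERK-regulated cell phenotype (proliferation, migration,
    survival).  The wiring beyond the constrained receptor/backbone
    degrees is a documented reconstruction — see docs/methods.md; the
    parallel adaptor route is what lets signal (and noise) amplify as it
    travels down the cascade.

    Edge weights are left unset; sample or assign them before simulating.
    """
    nodes = [
        ProteinNode("EGFR", "EGFR", "receptor"),
        ProteinNode("ERBB2", "ERBB2", "receptor"),
        ProteinNode("MET", "MET", "receptor"),
        ProteinNode("GRB2", "GRB2", "internal"),
        ProteinNode("AUX", "auxiliary adaptor", "internal"),
        ProteinNode("SOS", "SOS", "internal"),
        ProteinNode("RAS", "RAS", "internal"),
        ProteinNode("RAF", "RAF", "internal"),
        ProteinNode("MEK", "MEK", "internal"),
        ProteinNode("ERK", "ERK", "internal"),
        ProteinNode("Phenotype", "Phenotype", "terminal"),
    ]
    pairs = [
        ("EGFR", "GRB2"),
        ("EGFR", "AUX"),
        ("ERBB2", "GRB2"),
        ("ERBB2", "AUX"),
        ("MET", "GRB2"),
        ("MET", "AUX"),
        ("GRB2", "SOS"),
        ("AUX", "SOS"),
        ("AUX", "RAS"),
        ("SOS", "RAS"),
        ("RAS", "RAF"),
        ("RAF", "MEK"),
        ("MEK", "ERK"),
        ("ERK", "Phenotype"),
    ]
    edges = [WeightedEdge(s, t) for s, t in pairs]
    return SignalingNetwork(nodes, edges)


#: Backbone chain of the MAPK fixture, receptor-proximal to distal.
MAPK_BACKBONE = ["GRB2", "SOS", "RAS", "RAF", "MEK", "ERK"]


# -- weight assignment -------------------------------------------------


def sample_weights(
    net: SignalingNetwork, rng: np.random.Generator
) -> SignalingNetwork:
    """Independent U[0, 1] weight draw for every edge (new network)."""
    draws = rng.uniform(0.0, 1.0, size=len(net.edges))
    return net.with_weights(draws)


def set_uniform_weights(
    net: SignalingNetwork,
    value: float,
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> SignalingNetwork:
    """All weights set to ``value`` except per-edge ``overrides``."""
    overrides = dict(overrides or {})
    known_pairs = {(e.source, e.target) for e in net.edges}
    for pair in overrides:
        if pair not in known_pairs:
            raise KeyError(f"override for unknown edge {pair[0]}->{pair[1]}")
    weights = [
        overrides.get((e.source, e.target), value) for e in net.edges
    ]
    return net.with_weights(weights)


# -- file formats ------------------------------------------------------


def _default_weights_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".weights.tsv")


def load_network(
    path: str | Path,
    format: str,
    weights_path: str | Path | None = None,
) -> SignalingNetwork:
    """Read a network from ``path``.

    Formats
    -------
    ``sif``
        ``source<TAB>act<TAB>target`` per line; weights in a companion
        tab-separated file ``source<TAB>target<TAB>weight`` (default
        ``<path>.weights.tsv``; optional — weights stay unset without it).
    ``json``
        ``{"nodes": [{"id", "name", "role"}...],
        "edges": [{"source", "target", "weight"}...]}``; ``role`` and
        ``weight`` optional.
    ``edgelist``
        ``source<TAB>target<TAB>weight`` with ``#`` comments.
    """
    path = Path(path)
    if format == "sif":
        return _load_sif(path, weights_path)
    if format == "json":
        return _load_json(path)
    if format == "edgelist":
        return _load_edgelist(path)
    raise ValueError(f"unknown network format {format!r}")


def _parse_weight(token: str, context: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise NetworkParseError(f"{context}: bad weight {token!r}") from None


def _load_sif(path: Path, weights_path: str | Path | None) -> SignalingNetwork:
    pairs: list[tuple[str, str]] = []
    node_order: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected 'source {SIF_RELATION} target', "
                f"got {raw!r}"
            )
        src, rel, tgt = parts
        if rel != SIF_RELATION:
            raise NetworkParseError(
                f"{path}:{lineno}: unknown relation {rel!r} "
                f"(only {SIF_RELATION!r} is supported)"
            )
        pairs.append((src, tgt))
        for node in (src, tgt):
            if node not in node_order:
                node_order.append(node)
    weights: dict[tuple[str, str], float] = {}
    wpath = Path(weights_path) if weights_path else _default_weights_path(path)
    if wpath.exists():
        for lineno, raw in enumerate(wpath.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise NetworkParseError(
                    f"{wpath}:{lineno}: expected 'source target weight', "
                    f"got {raw!r}"
                )
            weights[(parts[0], parts[1])] = _parse_weight(
                parts[2], f"{wpath}:{lineno}"
            )
        unknown = set(weights) - set(pairs)
        if unknown:
            s, t = sorted(unknown)[0]
            raise NetworkValidationError(
                f"{wpath}: weight for edge {s}->{t} not present in {path}"
            )
    nodes = [ProteinNode(node_id) for node_id in node_order]
    edges = [WeightedEdge(s, t, weights.get((s, t))) for s, t in pairs]
    return SignalingNetwork(nodes, edges)


def _load_json(path: Path) -> SignalingNetwork:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"{path}: invalid JSON ({exc})") from None
    try:
        nodes = [
            ProteinNode(n["id"], n.get("name"), n.get("role"))
            for n in doc["nodes"]
        ]
        edges = [
            WeightedEdge(e["source"], e["target"], e.get("weight"))
            for e in doc["edges"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkParseError(f"{path}: missing field ({exc})") from None
    return SignalingNetwork(nodes, edges)


def _load_edgelist(path: Path) -> SignalingNetwork:
    node_order: list[str] = []
    edges: list[WeightedEdge] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected 'source target weight', got {raw!r}"
            )
        src, tgt, wtok = parts
        weight = _parse_weight(wtok, f"{path}:{lineno}")
        edges.append(WeightedEdge(src, tgt, weight))
        for node in (src, tgt):
            if node not in node_order:
                node_order.append(node)
    nodes = [ProteinNode(node_id) for node_id in node_order]
    return SignalingNetwork(nodes, edges)


def write_network(
    net: SignalingNetwork,
    path: str | Path,
    format: str,
    weights_path: str | Path | None = None,
) -> None:
    """Write ``net`` to ``path`` in one of the supported formats."""
    path = Path(path)
    if format == "sif":
        lines = [f"{e.source}\t{SIF_RELATION}\t{e.target}" for e in net.edges]
        path.write_text("\n".join(lines) + "\n")
        wpath = (
            Path(weights_path) if weights_path else _default_weights_path(path)
        )
        wlines = [
            f"{e.source}\t{e.target}\t{e.weight!r}"
            for e in net.edges
            if e.weight is not None
        ]
        if wlines:
            wpath.write_text("\n".join(wlines) + "\n")
    elif format == "json":
        doc = {
            "nodes": [
                {"id": n.id, "name": n.display_name, "role": net.role(n.id)}
                for n in net.nodes
            ],
            "edges": [
                {"source": e.source, "target": e.target, "weight": e.weight}
                for e in net.edges
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    elif format == "edgelist":
        lines = ["# source\ttarget\tweight"]
        for e in net.edges:
            if e.weight is None:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target} has no weight; the "
                    "edge-list format cannot represent unset weights"
                )
            lines.append(f"{e.source}\t{e.target}\t{e.weight!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")
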
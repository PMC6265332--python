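"""Two-cell communication links and multicellular signaling topologies.

A two-cell link is the minimal signaling unit: cell c1 senses peptide p1
through receptor g1 and, upon activation, secretes a non-cognate peptide p2
that cell c2 senses through its cognate receptor g2.  Links compose into
topologies (rings, buses, trees with OR-gate nodes), which are validated
against a crosstalk call matrix and simulated to steady state by fixed-point
iteration of the composed transfer functions.

Semantics are steady-state, matching endpoint fluorescence measurements; no
kinetics or spatial effects are modeled.  Secretion is summarized by a single
gain: the peptide concentration (nM) a fully activated sender contributes to
the shared medium (constitutive senders contribute the gain unconditionally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .curves import FourPL
from .orthogonality import CrosstalkCall

__all__ = [
    "TwoCellLink",
    "TransferFunction",
    "Node",
    "Topology",
    "ValidationReport",
    "SimulationResult",
    "enumerate_links",
    "compose_transfer",
    "validate_topology",
    "simulate_topology",
    "dropout_analysis",
]

ROLES = ("initiator", "linker", "or_gate", "reporter")
OR_MODES = ("max", "sum", "prob_or")


@dataclass(frozen=True)
class TwoCellLink:
    """Sender/receiver pair: receptor ``g1`` drives secretion of non-cognate
    peptide ``p2``, sensed by its cognate receptor ``g2``."""

    g1: str  # sender receptor (pair id)
    p1: str  # input peptide, cognate ligand of g1
    p2: str  # secreted peptide (non-cognate to g1)
    g2: str  # receiver receptor, cognate to p2
    gain: float = 5.0  # nM secreted at full sender activation
    promoter_mode: str = "inducible"  # or "constitutive"

    def __post_init__(self) -> None:
        if self.p2 == self.p1:
            raise ValueError("secreted peptide must be non-cognate to the sender receptor")


def enumerate_links(pair_ids: Sequence[str], gain: float = 5.0) -> list[TwoCellLink]:
    """All ordered sender/secreted-peptide combinations over orthogonal pairs.

    Pair i's receptor is cognate to pair i's ligand; every (g1=i, p2=j), j != i
    combination is a link, so n pairs yield n(n-1) links.
    """
    pairs = list(pair_ids)
    if len(pairs) < 2:
        raise ValueError("need at least 2 orthogonal pairs to form links")
    return [
        TwoCellLink(g1=a, p1=a, p2=b, g2=b, gain=gain)
        for a in pairs
        for b in pairs
        if b != a
    ]


@dataclass(frozen=True)
class TransferFunction:
    """Composed link response: p1 dose -> receiver response (afu/OD).

    response(d) = 4PL_g2( gain * activity_g1(d) ), with activity the sender's
    normalized (0-1) 4PL.  Monotone non-decreasing in dose.
    """

    g1: FourPL
    gain: float
    g2: FourPL

    def __call__(self, p1_dose):
        return self.g2.response(self.gain * self.g1.activity(p1_dose))


def compose_transfer(
    link: TwoCellLink, p1_dose, g1_params: FourPL, g2_params: FourPL
) -> float:
    """Predicted receiver response for a link at a given input dose."""
    if g1_params is None or g2_params is None:
        raise ValueError("both 4PL parameter sets are required")
    return TransferFunction(g1_params, link.gain, g2_params)(p1_dose)


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """A cell in a communication topology.

    ``receptors`` maps each sensed peptide to the receptor's 4PL parameters
    (1 receptor for plain nodes, exactly 2 for OR gates).  ``secretes`` is the
    outgoing peptide (None for pure reporters); constitutive nodes emit their
    gain unconditionally (ring initiators).
    """

    id: str
    role: str
    receptors: dict  # peptide id -> FourPL
    secretes: str | None = None
    gain: float = 5.0
    constitutive: bool = False
    readout: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "or_gate" and len(self.receptors) != 2:
            raise ValueError("or_gate nodes must express exactly 2 receptors")
        if self.role == "reporter" and not self.readout:
            self.readout = True
        if not self.constitutive and not (1 <= len(self.receptors) <= 2):
            raise ValueError("nodes express 1-2 receptors")


@dataclass
class Topology:
    """Directed communication graph over peptide-identified edges."""

    nodes: list
    external_inputs: dict = field(default_factory=dict)  # peptide -> dose (nM)
    kind: str = "custom"  # "ring" | "bus" | "tree" | "custom"
    or_mode: str = "max"

    def __post_init__(self) -> None:
        if self.or_mode not in OR_MODES:
            raise ValueError(f"or_mode must be one of {OR_MODES}")
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")

    def node(self, node_id: str) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def graph(self) -> nx.MultiDiGraph:
        """Producer -> consumer graph; edge key/attribute is the peptide."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(n.id for n in self.nodes)
        for prod in self.nodes:
            if prod.secretes is None:
                continue
            for cons in self.nodes:
                if prod.secretes in cons.receptors:
                    g.add_edge(prod.id, cons.id, peptide=prod.secretes)
        return g

    def to_json(self, path) -> None:
        doc = {
            "kind": self.kind,
            "or_mode": self.or_mode,
            "external_inputs": self.external_inputs,
            "nodes": [
                {
                    "id": n.id,
                    "role": n.role,
                    "receptors": {p: list(fp.as_tuple()) for p, fp in n.receptors.items()},
                    "secretes": n.secretes,
                    "gain": n.gain,
                    "constitutive": n.constitutive,
                    "readout": n.readout,
                }
                for n in self.nodes
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            doc = json.load(fh)
        nodes = [
            Node(
                id=d["id"],
                role=d["role"],
                receptors={p: FourPL(*v) for p, v in d["receptors"].items()},
                secretes=d.get("secretes"),
                gain=d.get("gain", 5.0),
                constitutive=d.get("constitutive", False),
                readout=d.get("readout", False),
            )
            for d in doc["nodes"]
        ]
        return cls(nodes, doc.get("external_inputs", {}), doc.get("kind", "custom"),
                   doc.get("or_mode", "max"))


@dataclass
class ValidationReport:
    violations: list  # (code, message)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_topology(
    t: Topology,
    call: CrosstalkCall | None = None,
    cognate_of: Mapping[str, str] | None = None,
) -> ValidationReport:
    """Structural and crosstalk validation of a topology.

    Checks that every consumed peptide has exactly one source (a single
    producing node or an external input), that no peptide present in the
    community cross-activates an unintended receptor according to ``call``
    (``cognate_of`` maps each peptide to its cognate receptor pair id in the
    call index), and, for ring topologies, that the producer/consumer graph is
    a single directed cycle covering all nodes.
    """
    violations: list[tuple[str, str]] = []

    producers: dict[str, list[str]] = {}
    for n in t.nodes:
        if n.secretes is not None:
            producers.setdefault(n.secretes, []).append(n.id)
    for p, dose in t.external_inputs.items():
        if dose > 0:
            producers.setdefault(p, []).append("<external>")

    consumed = {p: n.id for n in t.nodes for p in n.receptors}
    for p, consumer in consumed.items():
        src = producers.get(p, [])
        if not src:
            violations.append(("missing-signal", f"peptide {p} consumed by {consumer} has no source"))
        elif len(src) > 1:
            violations.append(
                ("duplicate-signal", f"peptide {p} produced by multiple sources: {src}")
            )

    if call is not None:
        if cognate_of is None:
            raise ValueError("cognate_of mapping required when a call matrix is given")
        index = {pid: i for i, pid in enumerate(call.pair_ids)}
        present = set(producers)
        for p in present.union(consumed):
            for n in t.nodes:
                for q in n.receptors:
                    if p == q:
                        continue
                    try:
                        i, j = index[cognate_of[q]], index[cognate_of[p]]
                    except KeyError as exc:
                        raise ValueError(f"unknown pair id in call index: {exc}") from exc
                    if call.calls[i, j]:
                        violations.append(
                            (
                                "cross-activation",
                                f"peptide {p} cross-activates receptor for {q} on node {n.id}",
                            )
                        )

    if t.kind == "ring":
        g = nx.DiGraph(t.graph())
        in_ok = all(g.in_degree(v) == 1 for v in g)
        out_ok = all(g.out_degree(v) == 1 for v in g)
        cycles = list(nx.simple_cycles(g)) if in_ok and out_ok else []
        if not (in_ok and out_ok and len(cycles) == 1 and len(cycles[0]) == len(t.nodes)):
            violations.append(("broken-cycle", "ring topology is not a single closed cycle"))

    return ValidationReport(violations)


# ---------------------------------------------------------------------------
# Steady-state simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    peptides: dict  # peptide id -> steady-state concentration (nM)
    activities: dict  # node id -> activity in [0, 1]
    reporter_outputs: dict  # node id -> afu/OD for readout nodes
    converged: bool
    iterations: int


def _node_activity(node: Node, peptides: Mapping[str, float], or_mode: str) -> float:
    acts = [fp.activity(peptides.get(p, 0.0)) for p, fp in node.receptors.items()]
    if not acts:
        return 0.0
    if len(acts) == 1:
        return float(acts[0])
    if or_mode == "max":
        return float(max(acts))
    if or_mode == "sum":
        return float(min(1.0, sum(acts)))
    return float(1.0 - (1.0 - acts[0]) * (1.0 - acts[1]))  # prob_or


def simulate_topology(
    t: Topology,
    inputs: Mapping[str, float] | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> SimulationResult:
    """Fixed-point steady state of a topology.

    Iterates peptide pools and node activities until the largest change falls
    below ``tol``.  Peptide pool for p = external dose + sum over producers of
    gain x activity (constitutive producers contribute gain unconditionally).
    Acyclic topologies converge in at most depth+1 iterations.  Non-convergence
    within ``max_iter`` is flagged and the partial state returned.
    """
    external = dict(t.external_inputs)
    if inputs:
        external.update(inputs)

    peptide_ids = {n.secretes for n in t.nodes if n.secretes} | set(external)
    peptides = {p: float(external.get(p, 0.0)) for p in peptide_ids}
    activities = {n.id: 0.0 for n in t.nodes}

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_act = {n.id: _node_activity(n, peptides, t.or_mode) for n in t.nodes}
        new_pep = {p: float(external.get(p, 0.0)) for p in peptide_ids}
        for n in t.nodes:
            if n.secretes is None:
                continue
            new_pep[n.secretes] += n.gain * (1.0 if n.constitutive else new_act[n.id])
        delta = max(
            max((abs(new_act[k] - activities[k]) for k in activities), default=0.0),
            max((abs(new_pep[k] - peptides[k]) for k in peptides), default=0.0),
        )
        activities, peptides = new_act, new_pep
        if delta < tol:
            converged = True
            break

    reporter_outputs = {}
    for n in t.nodes:
        if not n.readout:
            continue
        raw = [fp.response(peptides.get(p, 0.0)) for p, fp in n.receptors.items()]
        reporter_outputs[n.id] = float(max(raw)) if raw else 0.0
    return SimulationResult(peptides, activities, reporter_outputs, converged, iterations)


def dropout_analysis(
    t: Topology, inputs: Mapping[str, float] | None = None
) -> dict:
    """Reporter output of the full topology vs every single-node dropout.

    Returns a dict with the full-run result and, per dropped node, the dropout
    result and the reporter fold-change (full / dropout) for each readout node.
    """
    full = simulate_topology(t, inputs)
    out = {"full": full, "dropouts": {}}
    for n in t.nodes:
        reduced = Topology(
            [m for m in t.nodes if m.id != n.id],
            dict(t.external_inputs),
            kind="custom",
            or_mode=t.or_mode,
        )
        res = simulate_topology(reduced, inputs)
        fold = {
            rid: (full.reporter_outputs[rid] / res.reporter_outputs[rid])
            for rid in full.reporter_outputs
            if rid in res.reporter_outputs and res.reporter_outputs[rid] > 0
        }
        out["dropouts"][n.id] = {"result": res, "reporter_fold_change": fold}
    return out
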
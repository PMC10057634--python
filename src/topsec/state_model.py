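"""12-state class-HMM topology for merged transmembrane/secondary structure.

The hidden-state graph has four sub-models, one per structural class:

* ``M`` — membrane-spanning helix,
* ``H`` — non-membrane helix,
* ``E`` — non-membrane strand,
* ``C`` — non-membrane coil,

plus silent ``Begin`` and ``End`` boundary states.  M, H and E are each a
(begin, interior, end) triple whose interior self-loops, which encodes a
minimum segment length of three residues; C is a single self-looping state.
Every emitting state carries exactly one class label, so any state path
projects deterministically onto a label string over ``{M, H, C, E}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

CLASS_ALPHABET = "MHEC"

__all__ = [
    "State",
    "StateTopology",
    "TransitionModel",
    "build_default_topology",
    "validate_topology",
    "states_to_labels",
    "load_topology",
    "save_topology",
]


@dataclass(frozen=True)
class State:
    id: int
    name: str
    emitting: bool
    class_label: str | None  # one of M,H,C,E for emitting states, None for Begin/End


@dataclass
class StateTopology:
    """States plus the boolean mask of allowed directed transitions."""

    states: list[State]
    allowed: np.ndarray  # (n, n) bool, allowed[i, j] == i -> j permitted
    begin_id: int
    end_id: int

    # -- derived views ----------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def emitting_ids(self) -> np.ndarray:
        return np.array([s.id for s in self.states if s.emitting], dtype=int)

    @property
    def n_emitting(self) -> int:
        return int(sum(s.emitting for s in self.states))

    def class_of(self, state_id: int) -> str:
        s = self.states[state_id]
        if s.class_label is None:
            raise ValueError(f"state {s.name} (id {state_id}) carries no class label")
        return s.class_label

    def emitting_classes(self) -> np.ndarray:
        """Class label per emitting state, in emitting_ids order."""
        return np.array([s.class_label for s in self.states if s.emitting])

    def class_mask(self, label: str) -> np.ndarray:
        """Boolean mask over emitting states whose class equals ``label``."""
        if label not in CLASS_ALPHABET:
            raise ValueError(f"unknown class label {label!r}; expected one of {CLASS_ALPHABET}")
        return self.emitting_classes() == label

    def state_by_name(self, name: str) -> State:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)


def build_default_topology() -> StateTopology:
    """Default 12-state wiring.

    Begin feeds every sub-model entry; within each M/H/E triple the only
    edges are begin->interior, interior->interior and interior->end; each
    sub-model exit connects to every *other* sub-model's entry, to C and to
    End; C self-loops.
    """
    names = [
        ("Begin", False, None),
        ("M.begin", True, "M"),
        ("M.interior", True, "M"),
        ("M.end", True, "M"),
        ("H.begin", True, "H"),
        ("H.interior", True, "H"),
        ("H.end", True, "H"),
        ("E.begin", True, "E"),
        ("E.interior", True, "E"),
        ("E.end", True, "E"),
        ("C", True, "C"),
        ("End", False, None),
    ]
    states = [State(i, n, e, c) for i, (n, e, c) in enumerate(names)]
    idx = {s.name: s.id for s in states}
    allowed = np.zeros((12, 12), dtype=bool)

    entries = {"M": idx["M.begin"], "H": idx["H.begin"], "E": idx["E.begin"], "C": idx["C"]}
    exits = {"M": idx["M.end"], "H": idx["H.end"], "E": idx["E.end"], "C": idx["C"]}

    for e in entries.values():
        allowed[idx["Begin"], e] = True
    for cls in "MHE":
        b, i, e = entries[cls], idx[f"{cls}.interior"], exits[cls]
        allowed[b, i] = True
        allowed[i, i] = True
        allowed[i, e] = True
    for cls in "MHEC":
        ex = exits[cls]
        for other, entry in entries.items():
            if other != cls:
                allowed[ex, entry] = True
        allowed[ex, idx["C"]] = True  # C -> C self loop; M/H/E exits -> C already set
        allowed[ex, idx["End"]] = True
    return StateTopology(states=states, allowed=allowed, begin_id=idx["Begin"], end_id=idx["End"])


def _reachable(allowed: np.ndarray, start: int) -> set[int]:
    seen, stack = {start}, [start]
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(allowed[i]):
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return seen


def validate_topology(t: StateTopology) -> list[str]:
    """Return one message per violated invariant (empty list == valid)."""
    v: list[str] = []
    n = t.n_states
    if n != 12:
        v.append(f"state count != 12 (got {n})")
    silent = [s for s in t.states if not s.emitting]
    if len(silent) != 2:
        v.append(f"expected exactly 2 non-emitting states, got {len(silent)}")
    if t.allowed.shape != (n, n):
        v.append(f"allowed mask shape {t.allowed.shape} does not match {n} states")
        return v  # remaining checks need a square mask
    if t.allowed[:, t.begin_id].any():
        src = ", ".join(t.states[i].name for i in np.flatnonzero(t.allowed[:, t.begin_id]))
        v.append(f"Begin has incoming edges (from {src})")
    if t.allowed[t.end_id, :].any():
        dst = ", ".join(t.states[j].name for j in np.flatnonzero(t.allowed[t.end_id]))
        v.append(f"End has outgoing edges (to {dst})")
    for s in t.states:
        if s.emitting and s.class_label not in set(CLASS_ALPHABET):
            v.append(f"emitting state {s.name} has class {s.class_label!r}, not one of M,H,C,E")
        if not s.emitting and s.class_label is not None:
            v.append(f"silent state {s.name} carries class label {s.class_label!r}")
    fwd = _reachable(t.allowed, t.begin_id)
    bwd = _reachable(t.allowed.T, t.end_id)
    for s in t.states:
        if s.emitting and s.id not in fwd:
            v.append(f"state {s.name} unreachable from Begin")
        if s.emitting and s.id not in bwd:
            v.append(f"state {s.name} cannot reach End")
    return v


def states_to_labels(path: Sequence[int], t: StateTopology) -> str:
    """Project an emitting-state path onto its class-label string."""
    out = []
    for sid in path:
        s = t.states[sid]
        if not s.emitting:
            raise ValueError(f"malformed path: non-emitting state {s.name} (id {sid}) at position {len(out)}")
        out.append(s.class_label)
    return "".join(out)


# ---------------------------------------------------------------------------
# Transition parameters
# ---------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with an unconstrained logit backing.

    ``theta`` is the probability matrix used by the dynamic programs; it is
    always the row-wise softmax of ``logits`` restricted to allowed edges,
    so gradient steps in logit space can never leave the simplex or touch a
    disallowed edge.
    """

    logits: np.ndarray  # (n, n); only entries on allowed edges are meaningful
    topology: StateTopology
    theta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=float)
        if self.logits.shape != self.topology.allowed.shape:
            raise ValueError("logit matrix shape does not match topology")
        self.theta = self._normalize(self.logits)

    def _normalize(self, logits: np.ndarray) -> np.ndarray:
        allowed = self.topology.allowed
        theta = np.zeros_like(logits)
        for i in range(logits.shape[0]):
            cols = np.flatnonzero(allowed[i])
            if cols.size == 0:
                continue
            z = logits[i, cols] - logits[i, cols].max()
            w = np.exp(z)
            theta[i, cols] = w / w.sum()
        return theta

    @classmethod
    def uniform(cls, topology: StateTopology) -> "TransitionModel":
        return cls(np.zeros_like(topology.allowed, dtype=float), topology)

    @classmethod
    def from_theta(cls, theta: np.ndarray, topology: StateTopology, floor: float = 1e-12) -> "TransitionModel":
        """Build from an explicit probability matrix (renormalized per row)."""
        theta = np.asarray(theta, dtype=float)
        if (theta < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if (theta[~topology.allowed] != 0).any():
            raise ValueError("nonzero probability on a disallowed edge")
        logits = np.where(topology.allowed, np.log(np.maximum(theta, floor)), 0.0)
        return cls(logits, topology)

    def row_sums(self) -> np.ndarray:
        return self.theta.sum(axis=1)


# ---------------------------------------------------------------------------
# Plain-text (YAML) serialization
# ---------------------------------------------------------------------------


def save_topology(t: StateTopology, path) -> None:
    doc = {
        "states": [
            {"name": s.name, "emitting": s.emitting, "class": s.class_label} for s in t.states
        ],
        "begin": t.states[t.begin_id].name,
        "end": t.states[t.end_id].name,
        "edges": [
            [t.states[i].name, t.states[j].name]
            for i, j in zip(*np.nonzero(t.allowed))
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_topology(path) -> StateTopology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    states = [
        State(i, d["name"], bool(d["emitting"]), d.get("class"))
        for i, d in enumerate(doc["states"])
    ]
    idx = {s.name: s.id for s in states}
    n = len(states)
    allowed = np.zeros((n, n), dtype=bool)
    for a, b in doc["edges"]:
        allowed[idx[a], idx[b]] = True
    return StateTopology(states=states, allowed=allowed, begin_id=idx[doc["begin"]], end_id=idx[doc["end"]])


def default_topology_path():
    """Path of the shipped YAML config reproducing build_default_topology."""
    return resources.files("topsec").joinpath("data", "default_topology.yaml")
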
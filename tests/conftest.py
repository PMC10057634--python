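"""Shared fixtures: toy topologies and a brute-force path-enumeration oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from topsec.state_model import State, StateTopology, TransitionModel


def make_topology(classes: list[str], allowed_inner: np.ndarray | None = None) -> StateTopology:
    """Small fully-custom topology: Begin + one emitting state per entry of
    ``classes`` + End.  By default every emitting->emitting edge plus all
    Begin->state and state->End edges are allowed."""
    n = len(classes) + 2
    states = [State(0, "Begin", False, None)]
    states += [State(i + 1, f"S{i}", True, c) for i, c in enumerate(classes)]
    states.append(State(n - 1, "End", False, None))
    allowed = np.zeros((n, n), dtype=bool)
    k = len(classes)
    allowed[0, 1 : 1 + k] = True
    if allowed_inner is None:
        allowed[1 : 1 + k, 1 : 1 + k] = True
    else:
        allowed[1 : 1 + k, 1 : 1 + k] = allowed_inner
    allowed[1 : 1 + k, n - 1] = True
    return StateTopology(states=states, allowed=allowed, begin_id=0, end_id=n - 1)


def enumerate_paths(E: np.ndarray, theta: np.ndarray, t: StateTopology):
    """All (path, probability) pairs over emitting-state paths Begin->...->End.

    Brute force: probability of each path is the product of its transition
    and emission terms; independent of the DP implementation.
    """
    em = list(t.emitting_ids)
    L = E.shape[0]
    for combo in itertools.product(range(len(em)), repeat=L):
        p = theta[t.begin_id, em[combo[0]]] * E[0, combo[0]]
        for i in range(1, L):
            p *= theta[em[combo[i - 1]], em[combo[i]]] * E[i, combo[i]]
        p *= theta[em[combo[-1]], t.end_id]
        yield [em[k] for k in combo], p


def brute_force_logP(E, theta, t, labels: str | None = None) -> float:
    """-log of the summed path probability (optionally label-clamped)."""
    classes = t.emitting_classes()
    em = list(t.emitting_ids)
    tot = 0.0
    for path, p in enumerate_paths(E, theta, t):
        if labels is not None and any(
            classes[em.index(s)] != lab for s, lab in zip(path, labels)
        ):
            continue
        tot += p
    return np.inf if tot == 0 else -np.log(tot)


def brute_force_viterbi(E, theta, t):
    """argmax path with lowest-lexicographic tie-break, by enumeration."""
    best_p, best_path = -1.0, None
    for path, p in enumerate_paths(E, theta, t):
        if p > best_p + 1e-300 and not np.isclose(p, best_p, rtol=1e-12):
            if p > best_p:
                best_p, best_path = p, path
    return best_path, best_p


def raw_model(theta, t):
    """TransitionModel wrapper around an explicitly given (possibly
    unnormalized) matrix — used for finite differences on raw entries."""
    tm = TransitionModel.__new__(TransitionModel)
    tm.logits = np.zeros_like(theta)
    tm.topology = t
    tm.theta = np.asarray(theta, dtype=float)
    return tm


def random_instance(rng, max_states=5, max_len=6, min_len=1, dense=True):
    """Random small (topology, transition model, emission matrix) triple."""
    k = int(rng.integers(2, max_states + 1))
    classes = [rng.choice(list("MHCE")) for _ in range(k)]
    if dense:
        inner = np.ones((k, k), dtype=bool)
    else:
        inner = rng.random((k, k)) < 0.7
        np.fill_diagonal(inner, True)
    t = make_topology(classes, inner)
    logits = rng.normal(0, 1.5, size=(k + 2, k + 2))
    tm = TransitionModel(logits, t)
    L = int(rng.integers(min_len, max_len + 1))
    E = rng.random((L, k)) * 0.9 + 0.05
    return t, tm, E


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy():
    """The 2-emitting-state example model (classes M and C, obs in {0,1})."""
    t = make_topology(["M", "C"])
    theta = np.zeros((4, 4))
    theta[0, 1], theta[0, 2] = 0.6, 0.4
    theta[1, 1], theta[1, 2], theta[1, 3] = 0.7, 0.2, 0.1
    theta[2, 1], theta[2, 2], theta[2, 3] = 0.1, 0.8, 0.1
    tm = TransitionModel.from_theta(theta, t)
    emis = np.array([[0.9, 0.1], [0.2, 0.8]])  # state x symbol
    obs = [0, 1]
    E = np.array([[emis[0, o], emis[1, o]] for o in obs])
    return t, tm, E, theta
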
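"""Log-space dynamic programming over the class-HMM.

Implements the free-running and clamped forward/backward recursions, the
conditional-maximum-likelihood (CML) loss ``L = Lc - Lf`` with its exact
gradients, Viterbi decoding, and the simplex-safe transition update.

Conventions
-----------
* All recursions run in natural-log space; ``-inf`` encodes probability 0.
* Begin/End are silent: the Begin row of theta is the initial distribution
  over emitting states and the End column holds termination weights, so
  ``P(x | theta) = sum over paths Begin -> s_1 .. s_L -> End``.
* The clamped phase restricts position i to emitting states whose class
  equals the label ``y[i]``; hence ``P(x, y) <= P(x)`` and ``L >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .emission import EmissionTable
from .state_model import StateTopology, TransitionModel, states_to_labels

__all__ = [
    "CMLResult",
    "DecodeResult",
    "log_forward",
    "log_backward",
    "log_clamped_forward",
    "cml_loss",
    "viterbi",
    "update_transitions",
]


@dataclass
class CMLResult:
    Lf: float  # -log P(x | theta)
    Lc: float  # -log P(x, y | theta)
    L: float  # Lc - Lf = -log P(y | x, theta)
    grad_theta: np.ndarray  # (n_states, n_states), dL/d theta_ij, 0 off-mask
    grad_emissions: np.ndarray  # (length, n_emitting), dL/dE[i, k]


@dataclass
class DecodeResult:
    state_path: list[int]
    label_path: str
    log_score: float


def _check(E: EmissionTable, t: StateTopology) -> np.ndarray:
    scores = np.asarray(E.scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != t.n_emitting:
        raise ValueError(
            f"emission table has {scores.shape} scores; expected (L, {t.n_emitting})"
        )
    if scores.shape[0] == 0:
        raise ValueError("emission table is empty")
    if (scores < 0).any():
        raise ValueError("emission scores must be non-negative")
    return scores


def _log_parts(tm: TransitionModel, t: StateTopology):
    """Initial / inner / termination log-transition blocks over emitting states."""
    em = t.emitting_ids
    with np.errstate(divide="ignore"):
        log_a = np.log(tm.theta[t.begin_id, em])
        log_A = np.log(tm.theta[np.ix_(em, em)])
        log_w = np.log(tm.theta[em, t.end_id])
    return log_a, log_A, log_w


def _clamp_logE(logE: np.ndarray, y: str, t: StateTopology) -> np.ndarray:
    if len(y) != logE.shape[0]:
        raise ValueError(f"label string length {len(y)} != sequence length {logE.shape[0]}")
    classes = t.emitting_classes()
    out = np.full_like(logE, -np.inf)
    for i, lab in enumerate(y):
        mask = classes == lab
        if not mask.any():
            raise ValueError(f"label {lab!r} at position {i + 1} matches no emitting state")
        out[i, mask] = logE[i, mask]
    return out


def _forward(logE, log_a, log_A, log_w):
    L, K = logE.shape
    alpha = np.empty((L, K))
    alpha[0] = log_a + logE[0]
    for i in range(1, L):
        alpha[i] = logsumexp(alpha[i - 1][:, None] + log_A, axis=0) + logE[i]
    return alpha, logsumexp(alpha[-1] + log_w)


def _backward(logE, log_a, log_A, log_w):
    L, K = logE.shape
    beta = np.empty((L, K))
    beta[-1] = log_w
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(log_A + (logE[i + 1] + beta[i + 1])[None, :], axis=1)
    return beta, logsumexp(log_a + logE[0] + beta[0])


def log_forward(E: EmissionTable, tm: TransitionModel, t: StateTopology) -> float:
    """``Lf = -log P(x | theta)`` via the forward recursion (+inf if no path)."""
    scores = _check(E, t)
    with np.errstate(divide="ignore"):
        logE = np.log(scores)
    _, logP = _forward(logE, *_log_parts(tm, t))
    return float(-logP)


def log_backward(E: EmissionTable, tm: TransitionModel, t: StateTopology) -> float:
    """Same quantity as :func:`log_forward`, via the backward recursion."""
    scores = _check(E, t)
    with np.errstate(divide="ignore"):
        logE = np.log(scores)
    _, logP = _backward(logE, *_log_parts(tm, t))
    return float(-logP)


def log_clamped_forward(E: EmissionTable, tm: TransitionModel, t: StateTopology, y: str) -> float:
    """``Lc = -log P(x, y | theta)``: forward over label-consistent paths only."""
    scores = _check(E, t)
    with np.errstate(divide="ignore"):
        logE = np.log(scores)
    logEc = _clamp_logE(logE, y, t)
    _, logP = _forward(logEc, *_log_parts(tm, t))
    return float(-logP)


def _expected_counts(logE, log_a, log_A, log_w, alpha, beta, logP):
    """Posterior edge counts (begin row / inner block / end column) and state occupancies."""
    L, K = logE.shape
    with np.errstate(invalid="ignore"):
        gamma = np.exp(alpha + beta - logP)
    gamma = np.nan_to_num(gamma, nan=0.0, posinf=0.0)
    c_init = np.exp(np.nan_to_num(log_a + logE[0] + beta[0] - logP, nan=-np.inf))
    c_end = np.exp(np.nan_to_num(alpha[-1] + log_w - logP, nan=-np.inf))
    c_inner = np.zeros((K, K))
    for i in range(L - 1):
        with np.errstate(invalid="ignore"):
            xi = alpha[i][:, None] + log_A + (logE[i + 1] + beta[i + 1])[None, :] - logP
        c_inner += np.exp(np.nan_to_num(xi, nan=-np.inf))
    return c_init, c_inner, c_end, gamma


def _phase_counts(logE, parts):
    alpha, logP_f = _forward(logE, *parts)
    beta, logP_b = _backward(logE, *parts)
    logP = logP_f
    if not np.isfinite(logP):
        raise FloatingPointError("no allowed path has positive probability")
    return (*_expected_counts(logE, *parts, alpha, beta, logP), logP)


def cml_loss(E: EmissionTable, tm: TransitionModel, t: StateTopology, y: str) -> CMLResult:
    """CML loss and exact gradients from the clamped and free-running phases.

    ``grad_theta[i, j] = dL/d theta_ij = -(Cc_ij - Cf_ij) / theta_ij`` where
    ``C`` are posterior expected edge counts, and analogously
    ``grad_emissions[i, k] = -(gamma_c - gamma_f) / E[i, k]`` (0 where the
    occupancy is 0 in both phases).  Derivatives are taken with respect to
    the raw matrix entries, so they can be checked by finite differences
    without re-normalization.
    """
    scores = _check(E, t)
    with np.errstate(divide="ignore"):
        logE = np.log(scores)
    parts = _log_parts(tm, t)
    em = t.emitting_ids

    cf_init, cf_inner, cf_end, gamma_f, logPf = _phase_counts(logE, parts)
    logEc = _clamp_logE(logE, y, t)
    cc_init, cc_inner, cc_end, gamma_c, logPc = _phase_counts(logEc, parts)

    Lf, Lc = -logPf, -logPc
    n = t.n_states
    d_counts = np.zeros((n, n))
    d_counts[t.begin_id, em] = cc_init - cf_init
    d_counts[np.ix_(em, em)] = cc_inner - cf_inner
    d_counts[em, t.end_id] = cc_end - cf_end
    with np.errstate(divide="ignore", invalid="ignore"):
        grad_theta = np.where(t.allowed, -d_counts / tm.theta, 0.0)
    grad_theta = np.nan_to_num(grad_theta, nan=0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        grad_E = -(gamma_c - gamma_f) / scores
    grad_E = np.where((gamma_c == 0) & (gamma_f == 0), 0.0, grad_E)
    grad_E = np.nan_to_num(grad_E, nan=0.0)

    return CMLResult(Lf=float(Lf), Lc=float(Lc), L=float(Lc - Lf), grad_theta=grad_theta, grad_emissions=grad_E)


def viterbi(E: EmissionTable, tm: TransitionModel, t: StateTopology) -> DecodeResult:
    """Highest-log-score allowed path Begin -> ... -> End.

    Ties break toward the lowest state id at every backtrack step.
    """
    scores = _check(E, t)
    with np.errstate(divide="ignore"):
        logE = np.log(scores)
    log_a, log_A, log_w = _log_parts(tm, t)
    L, K = logE.shape
    delta = np.empty((L, K))
    psi = np.zeros((L, K), dtype=int)
    delta[0] = log_a + logE[0]
    for i in range(1, L):
        cand = delta[i - 1][:, None] + log_A
        psi[i] = np.argmax(cand, axis=0)  # first max == lowest emitting index
        delta[i] = cand[psi[i], np.arange(K)] + logE[i]
    final = delta[-1] + log_w
    best = int(np.argmax(final))
    log_score = float(final[best])
    if not np.isfinite(log_score):
        raise ValueError("no feasible path from Begin to End for this sequence")
    rev = [best]
    for i in range(L - 1, 0, -1):
        rev.append(int(psi[i, rev[-1]]))
    em = t.emitting_ids
    path = [int(em[k]) for k in reversed(rev)]
    return DecodeResult(state_path=path, label_path=states_to_labels(path, t), log_score=log_score)


def update_transitions(tm: TransitionModel, grad_theta: np.ndarray, eta: float) -> TransitionModel:
    """One gradient-descent step on the transition logits.

    ``grad_theta`` holds dL/d theta; the chain rule through the row-softmax
    gives ``dL/d logit_ij = theta_ij * (g_ij - sum_k theta_ik g_ik)``.  Rows
    re-normalize by construction and disallowed edges stay at 0.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if not np.isfinite(grad_theta[tm.topology.allowed]).all():
        raise ValueError("non-finite gradient entries on allowed edges")
    g = np.where(tm.topology.allowed, grad_theta, 0.0)
    row_dot = (tm.theta * g).sum(axis=1, keepdims=True)
    grad_logits = tm.theta * (g - row_dot)
    return TransitionModel(tm.logits - eta * grad_logits, tm.topology)
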
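"""Training regimes for the hybrid model.

Two regimes are provided:

* **separate** — the emission network is trained supervised (cross-entropy
  on per-residue state targets, early stopping on validation loss), its
  outputs are frozen, and the transition matrix is then fitted by
  conditional maximum likelihood (CML): gradient descent on
  ``L = Lc - Lf`` with safeguarded step-halving.
* **joint** — per-state sigmoid regressors and the CHMM are trained in
  alternation: each outer round takes one full-dataset CML step on the
  transitions, one gradient step on the emission parameters ``E_k``, forms
  the combined residual ``(T_k - E_k) + (T_k - e_k)`` against the 0/1
  label-consistency targets ``T_k``, trains the regressors for one epoch on
  its mean square (the joint loss ``L2``), and stops when validation
  accuracy stops rising.

Both entry points are pure functions of (data, config incl. seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chmm import DecodeResult, cml_loss, update_transitions, viterbi
from .dataset import LabeledSequence
from .emission import (
    EmissionNetworkConfig,
    EmissionTable,
    build_emission_network,
    emissions_from_posteriors,
)
from .encoding import encode_sequence, extract_windows
from .metrics import q_accuracy
from .state_model import (
    StateTopology,
    TransitionModel,
    build_default_topology,
    load_topology,
    save_topology,
)

__all__ = [
    "TrainingRunConfig",
    "TrainedModel",
    "train_emission_network",
    "fit_transitions_cml",
    "transitions_from_counts",
    "train_separate",
    "train_joint",
    "JointRoundState",
    "emission_argmax_labels",
]

_TIED_ORDER = sorted("MHCE")  # class-tied network output column order


@dataclass
class TrainingRunConfig:
    regime: str = "separate"  # or "joint"
    eta: float = 0.01  # transition step size (halved on safeguard retries)
    emission_eta: float = 0.1  # joint regime: step on the emission parameters E_k
    max_outer_rounds: int = 10  # joint regime outer alternations
    cml_max_iter: int = 500
    cml_tol: float = 1e-6
    patience: int = 10
    seed: int = 0
    validation_fraction: float = 0.1
    window: int = 19
    rescale: bool = False  # divide posteriors by state priors before decoding

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.regime not in ("separate", "joint"):
            raise ValueError(f"unknown regime {self.regime!r}")


# ---------------------------------------------------------------------------
# Feature / target assembly
# ---------------------------------------------------------------------------


def _windows_for(rec: LabeledSequence, window: int) -> np.ndarray:
    fm = encode_sequence(rec.sequence, rec.profile)
    return extract_windows(fm, window)


def _state_targets(labels: str, topology: StateTopology, soft: bool) -> np.ndarray:
    """Per-residue targets over emitting states.

    ``soft=True``: the class's probability mass split uniformly over its
    states (softmax training); ``soft=False``: 0/1 label-consistency
    indicators ``T_k`` (joint-regime regression targets).
    """
    classes = topology.emitting_classes()
    T = np.zeros((len(labels), classes.shape[0]))
    for lab in set(labels):
        mask = classes == lab
        rows = np.array([c == lab for c in labels])
        T[np.ix_(rows, mask)] = 1.0 / mask.sum() if soft else 1.0
    return T


def _tied_targets(labels: str) -> np.ndarray:
    col = {lab: i for i, lab in enumerate(_TIED_ORDER)}
    T = np.zeros((len(labels), 4))
    for i, lab in enumerate(labels):
        T[i, col[lab]] = 1.0
    return T


def _stack_dataset(data, topology, window, soft, class_tied=False):
    X = np.concatenate([_windows_for(r, window) for r in data]).astype(np.float32)
    if class_tied:
        T = np.concatenate([_tied_targets(r.labels) for r in data])
    else:
        T = np.concatenate([_state_targets(r.labels, topology, soft) for r in data])
    lengths = [len(r) for r in data]
    return X, T, lengths


def _class_posterior_acc(probs, data, topology, class_tied):
    """Accuracy of per-position argmax over class-summed posteriors."""
    if class_tied:
        classes = np.array(_TIED_ORDER)
        class_p = probs
    else:
        classes = np.array(sorted(set(topology.emitting_classes())))
        class_p = np.stack(
            [probs[:, topology.emitting_classes() == c].sum(axis=1) for c in classes], axis=1
        )
    pred = classes[np.argmax(class_p, axis=1)]
    true = np.array(list("".join(r.labels for r in data)))
    return float((pred == true).mean())


def _split(data, seed, fraction):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(round(fraction * len(data))))
    if n_val >= len(data):
        raise ValueError("dataset too small to hold out a validation split")
    val_idx = set(order[:n_val].tolist())
    train = [r for i, r in enumerate(data) if i not in val_idx]
    val = [r for i, r in enumerate(data) if i in val_idx]
    return train, val


# ---------------------------------------------------------------------------
# Supervised emission-network training
# ---------------------------------------------------------------------------


def train_emission_network(
    data: list[LabeledSequence],
    cfg: EmissionNetworkConfig,
    topology: StateTopology | None = None,
    window: int = 19,
    val_data: list[LabeledSequence] | None = None,
    val_fraction: float = 0.1,
):
    """Cross-entropy training with save-best weights and patience early stop.

    Returns ``(network, log)`` where the log has one dict per epoch with
    train loss, validation loss and validation (class-level) accuracy.
    """
    if not data:
        raise ValueError("empty training set")
    if any(r.labels is None for r in data):
        raise ValueError("all training sequences need labels")
    topology = topology or build_default_topology()
    rng = np.random.default_rng(cfg.seed)
    if val_data is None:
        data, val_data = _split(data, cfg.seed, val_fraction)
    X, T, _ = _stack_dataset(data, topology, window, soft=True, class_tied=cfg.class_tied)
    Xv, Tv, _ = _stack_dataset(val_data, topology, window, soft=True, class_tied=cfg.class_tied)
    net = build_emission_network(cfg, topology)
    best_loss, best_w, bad = np.inf, net.get_weights(), 0
    log = []
    N = X.shape[0]
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(N)
        losses = []
        for s in range(0, N, cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            losses.append(net.train_step(X[idx], T[idx]))
        val_loss = _batched_loss(net, Xv, Tv)
        val_acc = _class_posterior_acc(_batched_predict(net, Xv), val_data, topology, cfg.class_tied)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss, "val_acc": val_acc}
        )
        if val_loss < best_loss - 1e-12:
            best_loss, best_w, bad = val_loss, net.get_weights(), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    net.set_weights(best_w)
    return net, log


def _batched_predict(net, X, chunk=1024):
    if X.shape[0] == 0:
        return np.zeros((0, net.n_outputs))
    return np.concatenate([net.predict(X[s : s + chunk]) for s in range(0, X.shape[0], chunk)])


def _batched_loss(net, X, T, chunk=1024):
    tot, n = 0.0, 0
    for s in range(0, X.shape[0], chunk):
        p = net.predict(X[s : s + chunk])
        if net.cfg.head == "softmax_states":
            tot += float(-(T[s : s + chunk] * np.log(np.maximum(p, 1e-300))).sum())
        else:
            tot += float(((T[s : s + chunk] - p) ** 2).sum())
        n += p.shape[0]
    return tot / max(n, 1)


# ---------------------------------------------------------------------------
# Batched dataset-level CML (transition fitting)
# ---------------------------------------------------------------------------


def _lse(M: np.ndarray, axis: int) -> np.ndarray:
    m = M.max(axis=axis)
    ms = np.where(np.isfinite(m), m, 0.0)
    s = np.exp(M - np.expand_dims(ms, axis)).sum(axis=axis)
    with np.errstate(divide="ignore"):
        return np.where(s > 0, ms + np.log(s), -np.inf)


class _RaggedBatch:
    """Variable-length sequences padded to a common grid, sorted by length
    descending so each DP step operates on a contiguous active prefix."""

    def __init__(self, data, emissions, topology):
        classes = topology.emitting_classes()
        order = sorted(range(len(data)), key=lambda i: -len(data[i]))
        self.lengths = np.array([len(data[i]) for i in order])
        B, Lmax, K = len(order), int(self.lengths[0]), classes.shape[0]
        self.logE = np.full((B, Lmax, K), -np.inf)
        self.logEc = np.full((B, Lmax, K), -np.inf)
        self.logE_rev = np.full((B, Lmax, K), -np.inf)
        self.logEc_rev = np.full((B, Lmax, K), -np.inf)
        for b, i in enumerate(order):
            with np.errstate(divide="ignore"):
                le = np.log(emissions[i].scores)
            mask = np.array([classes == c for c in data[i].labels])
            lec = np.where(mask, le, -np.inf)
            L = le.shape[0]
            self.logE[b, :L] = le
            self.logEc[b, :L] = lec
            self.logE_rev[b, :L] = le[::-1]
            self.logEc_rev[b, :L] = lec[::-1]
        # active[i] = number of sequences with length > i
        self.active = np.array([(self.lengths > i).sum() for i in range(Lmax)])
        idx = np.arange(Lmax)[None, :]
        self.unrev = np.clip(self.lengths[:, None] - 1 - idx, 0, None)  # (B, Lmax)

    def phase(self, clamped, log_a, log_A, log_w):
        """One forward-backward pass; returns (-sum logP, edge/boundary counts)."""
        logE = self.logEc if clamped else self.logE
        logE_rev = self.logEc_rev if clamped else self.logE_rev
        B, Lmax, K = logE.shape
        alpha = np.full((B, Lmax, K), -np.inf)
        alpha[:, 0] = log_a + logE[:, 0]
        for i in range(1, Lmax):
            n = self.active[i]
            if n == 0:
                break
            alpha[:n, i] = _lse(alpha[:n, i - 1, :, None] + log_A, axis=1) + logE[:n, i]
        last = alpha[np.arange(B), self.lengths - 1]
        logP = _lse(last + log_w, axis=1)
        if not np.isfinite(logP).all():
            raise FloatingPointError("a sequence admits no allowed path (or no label-consistent path)")
        betar = np.full((B, Lmax, K), -np.inf)
        betar[:, 0] = log_w
        for r in range(1, Lmax):
            n = self.active[r]
            if n == 0:
                break
            betar[:n, r] = _lse(log_A[None] + (logE_rev[:n, r - 1] + betar[:n, r - 1])[:, None, :], axis=2)
        beta = np.take_along_axis(betar, self.unrev[:, :, None], axis=1)
        c_init = np.exp(log_a + logE[:, 0] + beta[:, 0] - logP[:, None]).sum(axis=0)
        c_end = np.exp(last + log_w - logP[:, None]).sum(axis=0)
        c_inner = np.zeros((K, K))
        for i in range(Lmax - 1):
            n = self.active[i + 1]
            if n == 0:
                break
            xi = (
                alpha[:n, i, :, None]
                + log_A
                + (logE[:n, i + 1] + beta[:n, i + 1])[:, None, :]
                - logP[:n, None, None]
            )
            c_inner += np.exp(xi).sum(axis=0)
        return float(-logP.sum()), c_init, c_inner, c_end


def _dataset_cml(batch, tm, topology):
    """Total L = sum(Lc - Lf) and dL/d theta summed over the dataset."""
    em = topology.emitting_ids
    with np.errstate(divide="ignore"):
        log_a = np.log(tm.theta[topology.begin_id, em])
        log_A = np.log(tm.theta[np.ix_(em, em)])
        log_w = np.log(tm.theta[em, topology.end_id])
    n = topology.n_states
    d = np.zeros((n, n))
    Lf, fi, fA, fw = batch.phase(False, log_a, log_A, log_w)
    Lc, ci, cA, cw = batch.phase(True, log_a, log_A, log_w)
    d[topology.begin_id, em] = ci - fi
    d[np.ix_(em, em)] = cA - fA
    d[em, topology.end_id] = cw - fw
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = np.where(topology.allowed, -d / tm.theta, 0.0)
    return Lc - Lf, np.nan_to_num(grad, nan=0.0)


def transitions_from_counts(
    data: list[LabeledSequence],
    emissions: list[EmissionTable],
    topology: StateTopology,
    pseudocount: float = 1.0,
) -> TransitionModel:
    """Supervised initialization: expected label-consistent edge counts.

    Runs one clamped forward-backward under uniform transitions and
    normalizes the posterior edge counts (plus a pseudocount on allowed
    edges) into a stochastic matrix — the usual way to seed HMM transition
    training when per-residue labels are available.
    """
    batch = _RaggedBatch(data, emissions, topology)
    tm_u = TransitionModel.uniform(topology)
    em = topology.emitting_ids
    with np.errstate(divide="ignore"):
        log_a = np.log(tm_u.theta[topology.begin_id, em])
        log_A = np.log(tm_u.theta[np.ix_(em, em)])
        log_w = np.log(tm_u.theta[em, topology.end_id])
    _, ci, cA, cw = batch.phase(True, log_a, log_A, log_w)
    n = topology.n_states
    counts = np.zeros((n, n))
    counts[topology.begin_id, em] = ci
    counts[np.ix_(em, em)] = cA
    counts[em, topology.end_id] = cw
    counts += pseudocount * topology.allowed
    theta = np.where(topology.allowed, counts, 0.0)
    sums = theta.sum(axis=1, keepdims=True)
    theta = np.divide(theta, sums, out=np.zeros_like(theta), where=sums > 0)
    return TransitionModel.from_theta(theta, topology)


def fit_transitions_cml(
    data: list[LabeledSequence],
    emissions: list[EmissionTable],
    tm0: TransitionModel,
    cfg: TrainingRunConfig,
):
    """CML gradient descent on the transition matrix over a whole dataset.

    Safeguarded fixed-step descent: the step size starts at ``cfg.eta``
    and is halved (with the step retried) whenever the summed loss would
    increase, so the recorded loss trace is non-increasing.  Stops on
    ``cfg.cml_tol`` relative loss change or ``cfg.cml_max_iter``
    iterations.  Returns ``(tm, trace)``.
    """
    if not data:
        raise ValueError("empty dataset")
    if len(emissions) != len(data):
        raise ValueError("one emission table per sequence required")
    topology = tm0.topology
    batch = _RaggedBatch(data, emissions, topology)
    n_seq = len(data)
    tm = tm0
    loss, grad = _dataset_cml(batch, tm, topology)
    trace = [loss]
    eta = cfg.eta
    for _ in range(cfg.cml_max_iter):
        stepped = False
        for _ in range(40):  # halvings before giving up on this iteration
            cand = update_transitions(tm, grad / n_seq, eta)
            cand_loss, cand_grad = _dataset_cml(batch, cand, topology)
            if cand_loss <= loss + 1e-12:
                stepped = True
                break
            eta /= 2.0
        if not stepped:
            break
        improved = loss - cand_loss
        tm, loss, grad = cand, cand_loss, cand_grad
        trace.append(loss)
        if improved < cfg.cml_tol * max(1.0, abs(loss)):
            break
    return tm, trace


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Predict-ready bundle: topology + transitions + emission provider."""

    topology: StateTopology
    tm: TransitionModel
    net: object
    net_cfg: EmissionNetworkConfig
    run_cfg: TrainingRunConfig
    priors: np.ndarray  # marginal state frequencies on the training labels
    training_log: dict = field(default_factory=dict)

    def emission_table(self, seq: str, profile: np.ndarray | None = None) -> EmissionTable:
        fm = encode_sequence(seq, profile)
        windows = extract_windows(fm, self.run_cfg.window)
        table = EmissionTable(
            _batched_predict(self.net, windows),
            provider_tag="softmax" if self.net_cfg.head == "softmax_states" else "sigmoid",
        )
        if self.net_cfg.class_tied:
            classes = self.topology.emitting_classes()
            col = {lab: i for i, lab in enumerate(_TIED_ORDER)}
            table = EmissionTable(table.scores[:, [col[c] for c in classes]], table.provider_tag)
        if self.run_cfg.rescale:
            table = emissions_from_posteriors(table, self.priors, rescale=True)
        return table

    def predict(self, seq: str, profile: np.ndarray | None = None) -> DecodeResult:
        return viterbi(self.emission_table(seq, profile), self.tm, self.topology)

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_topology(self.topology, directory / "topology.yaml")
        np.savetxt(directory / "theta.tsv", self.tm.theta, delimiter="\t", fmt="%.17g")
        np.savez(directory / "network.npz", *self.net.get_weights())
        cfg = {
            "net_cfg": asdict(self.net_cfg),
            "run_cfg": asdict(self.run_cfg),
            "priors": self.priors.tolist(),
            "version": __version__,
        }
        cfg["config_hash"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        (directory / "manifest.json").write_text(json.dumps(cfg, indent=1))
        (directory / "training_log.json").write_text(
            json.dumps(self.training_log, indent=1, default=float)
        )
        net_log = self.training_log.get("network")
        if net_log:
            with open(directory / "training_log.csv", "w") as fh:
                fh.write("epoch,train_loss,val_loss,val_acc\n")
                for row in net_log:
                    fh.write(
                        f"{row['epoch']},{row['train_loss']:.8g},{row['val_loss']:.8g},{row['val_acc']:.8g}\n"
                    )

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        topology = load_topology(directory / "topology.yaml")
        theta = np.loadtxt(directory / "theta.tsv", delimiter="\t")
        tm = TransitionModel.from_theta(np.where(topology.allowed, theta, 0.0), topology)
        nc = manifest["net_cfg"]
        nc["conv_layers"] = [tuple(x) for x in nc["conv_layers"]]
        nc["fc_units"] = tuple(nc["fc_units"])
        net_cfg = EmissionNetworkConfig(**nc)
        run_cfg = TrainingRunConfig(**manifest["run_cfg"])
        net = build_emission_network(net_cfg, topology)
        with np.load(directory / "network.npz") as z:
            net.set_weights([z[k] for k in z.files])
        log = json.loads((directory / "training_log.json").read_text())
        return cls(
            topology=topology,
            tm=tm,
            net=net,
            net_cfg=net_cfg,
            run_cfg=run_cfg,
            priors=np.array(manifest["priors"]),
            training_log=log,
        )


def _state_priors(data, topology) -> np.ndarray:
    """Marginal emitting-state frequencies implied by the training labels
    (class frequency split uniformly over the class's states)."""
    classes = topology.emitting_classes()
    counts = np.zeros(classes.shape[0])
    total = 0
    for r in data:
        for lab in r.labels:
            mask = classes == lab
            counts[mask] += 1.0 / mask.sum()
            total += 1
    return counts / total


def emission_argmax_labels(table: EmissionTable, topology: StateTopology) -> str:
    """Per-position baseline: argmax over class-summed emission scores."""
    classes = topology.emitting_classes()
    labs = sorted(set(classes))
    class_scores = np.stack([table.scores[:, classes == c].sum(axis=1) for c in labs], axis=1)
    return "".join(labs[i] for i in np.argmax(class_scores, axis=1))


# ---------------------------------------------------------------------------
# Regimes
# ---------------------------------------------------------------------------


def train_separate(
    data: list[LabeledSequence],
    cfg: TrainingRunConfig,
    net_cfg: EmissionNetworkConfig | None = None,
    topology: StateTopology | None = None,
) -> TrainedModel:
    """Supervised emission network, then CML on the transitions."""
    topology = topology or build_default_topology()
    net_cfg = net_cfg or EmissionNetworkConfig(seed=cfg.seed)
    train, val = _split(data, cfg.seed, cfg.validation_fraction)
    net, net_log = train_emission_network(train, net_cfg, topology, cfg.window, val_data=val)
    priors = _state_priors(train, topology)
    emissions = []
    for r in train:
        table = EmissionTable(_batched_predict(net, _windows_for(r, cfg.window)), "softmax")
        if cfg.rescale:
            table = emissions_from_posteriors(table, priors, rescale=True)
        emissions.append(table)
    tm0 = transitions_from_counts(train, emissions, topology)
    tm, trace = fit_transitions_cml(train, emissions, tm0, cfg)
    return TrainedModel(
        topology=topology,
        tm=tm,
        net=net,
        net_cfg=net_cfg,
        run_cfg=cfg,
        priors=priors,
        training_log={"network": net_log, "cml_trace": trace},
    )


@dataclass
class JointRoundState:
    """State of one joint-training alternation.

    ``E_k`` holds the emission parameters after the CHMM iteration (one
    gradient step away from the regressor outputs ``e_k``), ``T_k`` the 0/1
    label-consistency targets, ``error_table`` the combined residual
    ``(T_k - E_k) + (T_k - e_k)``, and ``L2`` its mean square.
    """

    E_k: np.ndarray  # (positions, states)
    T_k: np.ndarray  # (positions, states), entries in {0, 1}
    error_table: np.ndarray
    L2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.L2) or self.L2 < 0:
            raise FloatingPointError(f"joint loss L2 = {self.L2} is not a finite non-negative number")


def _joint_round(train, e_all, T, bounds, tm, topology, cfg, eps):
    """One CHMM iteration of the alternation: full-dataset step on theta,
    one step on E_k, and the combined-error bookkeeping."""
    grad_theta = np.zeros_like(tm.theta)
    E_upd = np.empty_like(e_all)
    for j, r in enumerate(train):
        sl = slice(bounds[j], bounds[j + 1])
        res = cml_loss(EmissionTable(e_all[sl], "sigmoid"), tm, topology, r.labels)
        grad_theta += res.grad_theta
        E_upd[sl] = np.clip(e_all[sl] - cfg.emission_eta * res.grad_emissions, eps, 1 - eps)
    tm_new = update_transitions(tm, grad_theta / len(train), cfg.eta)
    error = (T - E_upd) + (T - e_all)
    state = JointRoundState(E_k=E_upd, T_k=T, error_table=error, L2=float((error**2).mean()))
    return tm_new, state


def train_joint(
    data: list[LabeledSequence],
    cfg: TrainingRunConfig,
    net_cfg: EmissionNetworkConfig | None = None,
    topology: StateTopology | None = None,
) -> TrainedModel:
    """Alternating joint training of per-state regressors and the CHMM."""
    topology = topology or build_default_topology()
    net_cfg = net_cfg or EmissionNetworkConfig(
        head="sigmoid_per_state",
        conv_layers=[(16, 3)],
        lstm_units=8,
        fc_units=(32, 16),
        seed=cfg.seed,
    )
    if net_cfg.head != "sigmoid_per_state":
        raise ValueError("joint training needs the sigmoid_per_state head")
    train, val = _split(data, cfg.seed, cfg.validation_fraction)
    rng = np.random.default_rng(cfg.seed)
    X, T, lengths = _stack_dataset(train, topology, cfg.window, soft=False)
    net = build_emission_network(net_cfg, topology)
    tm = TransitionModel.uniform(topology)
    bounds = np.cumsum([0] + lengths)
    eps = 1e-6
    l2_trace, acc_trace = [], []
    best = (-np.inf, net.get_weights(), tm)
    bad = 0
    for _ in range(cfg.max_outer_rounds):
        e_all = np.clip(_batched_predict(net, X), eps, 1 - eps)
        tm, state = _joint_round(train, e_all, T, bounds, tm, topology, cfg, eps)
        residual = T - state.E_k
        l2_trace.append(state.L2)
        # one epoch of regressor training against the combined error
        perm = rng.permutation(X.shape[0])
        for s in range(0, X.shape[0], net_cfg.batch_size):
            idx = perm[s : s + net_cfg.batch_size]
            net.train_step(X[idx], T[idx], residual=residual[idx])
        # validation accuracy via full decoding
        acc = _joint_val_acc(net, tm, topology, val, cfg.window, eps)
        acc_trace.append(acc)
        if acc > best[0] + 1e-9:
            best, bad = (acc, net.get_weights(), tm), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    net.set_weights(best[1])
    tm = best[2]
    return TrainedModel(
        topology=topology,
        tm=tm,
        net=net,
        net_cfg=net_cfg,
        run_cfg=cfg,
        priors=_state_priors(train, topology),
        training_log={"l2_trace": l2_trace, "val_acc": acc_trace},
    )


def _joint_val_acc(net, tm, topology, val, window, eps):
    accs = []
    for r in val:
        table = EmissionTable(np.clip(_batched_predict(net, _windows_for(r, window)), eps, 1 - eps), "sigmoid")
        accs.append(q_accuracy(viterbi(table, tm, topology).label_path, r.labels))
    return float(np.mean(accs))
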
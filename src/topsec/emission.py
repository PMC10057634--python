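"""Emission-score providers for the class-HMM dynamic programs.

The DP layer consumes an :class:`EmissionTable` — a (positions x emitting
states) matrix of non-negative scores — and does not care where it came
from.  Three interchangeable providers are offered:

* :func:`table_emission` — classical per-class residue distributions
  (turns the hybrid model into an ordinary HMM; used as the testing oracle
  and by the synthetic generator);
* a softmax network over all emitting states (separate-training regime);
* per-state sigmoid regressors (joint-training regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._network import EmissionNetwork
from .state_model import StateTopology

__all__ = [
    "EmissionTable",
    "EmissionNetworkConfig",
    "table_emission",
    "build_emission_network",
    "predict_emissions",
    "emissions_from_posteriors",
]


@dataclass
class EmissionTable:
    scores: np.ndarray  # (length, n_emitting), non-negative
    provider_tag: str = "table"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("emission scores must be non-negative")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def to_tsv(self, path, topology: StateTopology | None = None) -> None:
        """Debug export: positions x emitting-state scores."""
        if topology is not None:
            names = [topology.states[i].name for i in topology.emitting_ids]
        else:
            names = [f"state{k}" for k in range(self.scores.shape[1])]
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(names) + "\n")
            for i, row in enumerate(self.scores, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class EmissionNetworkConfig:
    """Architecture and optimisation settings for the neural providers.

    ``head`` selects the output arity: ``softmax_states`` emits one
    probability vector over all emitting states, ``sigmoid_per_state`` one
    independent (0,1) regressor per emitting state.  ``class_tied`` instead
    outputs one value per class, broadcast to the class's states.
    """

    conv_layers: list[tuple[int, int]] = field(default_factory=lambda: [(32, 3)])
    lstm_units: int = 16
    attention: bool = True
    fc_units: tuple[int, int] = (32, 16)
    head: str = "softmax_states"
    class_tied: bool = False
    seed: int = 0
    learning_rate: float = 2e-3
    batch_size: int = 64
    max_epochs: int = 40
    patience: int = 10

    def __post_init__(self) -> None:
        if self.head not in ("softmax_states", "sigmoid_per_state"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def table_emission(class_dists: dict[str, np.ndarray], obs, t: StateTopology) -> EmissionTable:
    """Classical HMM emissions from per-class residue distributions.

    ``class_dists`` maps each class label to a 20-vector over the residue
    alphabet (must sum to 1 within 1e-9).  States of the same class share a
    column profile.
    """
    idx = np.asarray(getattr(obs, "indices", obs), dtype=int)
    classes = t.emitting_classes()
    for lab in np.unique(classes):
        d = np.asarray(class_dists[lab], dtype=float)
        if abs(d.sum() - 1.0) > 1e-9:
            raise ValueError(f"class {lab!r} distribution sums to {d.sum():.12f}, not 1")
    scores = np.empty((idx.shape[0], classes.shape[0]))
    for k, lab in enumerate(classes):
        scores[:, k] = np.asarray(class_dists[lab], dtype=float)[idx]
    return EmissionTable(scores, provider_tag="table")


def build_emission_network(cfg: EmissionNetworkConfig, t: StateTopology, n_features: int = 52) -> EmissionNetwork:
    """Trainable window->emission network with the arity the config asks for."""
    n_out = 4 if cfg.class_tied else t.n_emitting
    return EmissionNetwork(cfg, n_features=n_features, n_outputs=n_out)


def predict_emissions(net: EmissionNetwork, windows: np.ndarray, t: StateTopology | None = None) -> EmissionTable:
    """Run the network over per-residue windows; one table row per window.

    For a class-tied network a topology must be supplied so the 4 class
    outputs can be broadcast to the corresponding emitting states.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError(f"expected (n, window, features) windows, got shape {windows.shape}")
    probs = net.predict(windows)
    if net.cfg.class_tied:
        if t is None:
            raise ValueError("class-tied networks need a topology to map classes to states")
        from .state_model import CLASS_ALPHABET

        classes = t.emitting_classes()
        col = {lab: i for i, lab in enumerate(sorted(set(CLASS_ALPHABET)))}
        probs = probs[:, [col[lab] for lab in classes]]
    tag = "softmax" if net.cfg.head == "softmax_states" else "sigmoid"
    return EmissionTable(probs, provider_tag=tag)


def emissions_from_posteriors(post_table: EmissionTable, priors: np.ndarray, rescale: bool = True) -> EmissionTable:
    """Scaled-likelihood conversion: divide state posteriors by state priors.

    Standard hybrid-HMM practice: with p(state | window) from a classifier
    and marginal state frequencies ``priors``, p(window | state) is
    proportional to posterior / prior.  ``rescale=False`` returns an
    identity copy (posteriors used directly as emissions).
    """
    priors = np.asarray(priors, dtype=float)
    if not rescale:
        return EmissionTable(post_table.scores.copy(), provider_tag=post_table.provider_tag)
    if priors.shape != (post_table.scores.shape[1],):
        raise ValueError("priors length must equal the number of emitting states")
    if (priors <= 0).any() and (post_table.scores[:, priors <= 0] != 0).any():
        raise ValueError("zero prior with nonzero posterior mass")
    safe = np.where(priors > 0, priors, 1.0)
    return EmissionTable(post_table.scores / safe, provider_tag=post_table.provider_tag + "/prior")
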
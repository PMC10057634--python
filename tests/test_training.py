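"""Small-scale training behaviour: supervised emissions, CML fitting, bundles.

The heavier end-to-end properties (parameter recovery at full size, the
complete separate/joint pipelines) live in the acceptance suite; here the
same machinery is exercised on corpora small enough to run in seconds.
"""

import numpy as np
import pytest

from topsec.dataset import LabeledSequence
from topsec.emission import EmissionNetworkConfig, EmissionTable, table_emission
from topsec.encoding import AMINO_ACIDS, encode_observations
from topsec.metrics import q_accuracy
from topsec.state_model import TransitionModel, build_default_topology
from topsec.synthetic import default_generative_model, simulate_dataset
from topsec.training import (
    TrainingRunConfig,
    _state_targets,
    fit_transitions_cml,
    train_emission_network,
    train_joint,
    train_separate,
    transitions_from_counts,
)


@pytest.fixture(scope="module")
def gm():
    return default_generative_model(seed=1)


@pytest.fixture(scope="module")
def small_corpus(gm):
    return simulate_dataset(gm, 40, (60, 120), seed=1)


def tabular_emissions(records, gm):
    return [
        table_emission(gm.class_dists, encode_observations(r.sequence), gm.topology)
        for r in records
    ]


class TestTargets:
    def test_soft_targets_split_class_mass(self):
        t = build_default_topology()
        T = _state_targets("MC", t, soft=True)
        classes = t.emitting_classes()
        assert np.allclose(T[0, classes == "M"], 1 / 3)
        assert np.allclose(T[0, classes != "M"], 0.0)
        assert T[1, classes == "C"] == pytest.approx(1.0)
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_hard_targets_are_indicators(self):
        t = build_default_topology()
        T = _state_targets("MC", t, soft=False)
        classes = t.emitting_classes()
        assert (T[0, classes == "M"] == 1.0).all()
        assert set(np.unique(T)) <= {0.0, 1.0}


class TestEmissionNetworkTraining:
    def test_separable_classes_reach_high_validation_accuracy(self, gm):
        # disjoint class alphabets: the window classifier should become
        # nearly perfect within a few epochs
        g = default_generative_model(seed=1, separation=1.0)
        ds = simulate_dataset(g, 30, (60, 90), seed=2)
        cfg = EmissionNetworkConfig(
            conv_layers=[(16, 3)], lstm_units=8, fc_units=(16, 12), seed=2, max_epochs=20
        )
        net, log = train_emission_network(ds.records, cfg, g.topology)
        assert log[-1]["val_acc"] > 0.95

    def test_same_seed_identical_log(self, small_corpus, gm):
        cfg = EmissionNetworkConfig(conv_layers=[(8, 3)], lstm_units=4, fc_units=(12, 8), seed=5, max_epochs=3)
        _, log1 = train_emission_network(small_corpus.records[:10], cfg, gm.topology)
        _, log2 = train_emission_network(small_corpus.records[:10], cfg, gm.topology)
        assert log1 == log2

    def test_best_weights_kept_not_last(self, small_corpus, gm):
        cfg = EmissionNetworkConfig(
            conv_layers=[(8, 3)], lstm_units=4, fc_units=(12, 8), seed=5, max_epochs=8, patience=2
        )
        net, log = train_emission_network(small_corpus.records[:10], cfg, gm.topology)
        best_epoch = min(log, key=lambda e: e["val_loss"])["epoch"]
        # if training stopped past the best epoch, the retained weights must
        # reproduce the best validation loss, not the final one
        from topsec.training import _batched_loss, _stack_dataset, _split

        data, val = _split(small_corpus.records[:10], cfg.seed, 0.1)
        Xv, Tv, _ = _stack_dataset(val, gm.topology, 19, soft=True)
        assert _batched_loss(net, Xv, Tv) == pytest.approx(log[best_epoch]["val_loss"])

    def test_empty_data_rejected(self, gm):
        with pytest.raises(ValueError, match="empty"):
            train_emission_network([], EmissionNetworkConfig(), gm.topology)


class TestFitTransitionsCML:
    def test_trace_non_increasing(self, small_corpus, gm):
        emis = tabular_emissions(small_corpus.records, gm)
        cfg = TrainingRunConfig(seed=1, cml_max_iter=30)
        _, trace = fit_transitions_cml(
            small_corpus.records, emis, TransitionModel.uniform(gm.topology), cfg
        )
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_start_at_truth_changes_little(self, small_corpus, gm):
        emis = tabular_emissions(small_corpus.records, gm)
        cfg = TrainingRunConfig(seed=1, cml_max_iter=5)
        _, trace = fit_transitions_cml(small_corpus.records, emis, gm.theta_star, cfg)
        # relative improvement from the generative optimum is marginal
        assert (trace[0] - trace[-1]) / abs(trace[0]) < 0.01

    def test_counts_initialization_close_to_truth(self, small_corpus, gm):
        emis = tabular_emissions(small_corpus.records, gm)
        tm0 = transitions_from_counts(small_corpus.records, emis, gm.topology)
        err = np.abs(tm0.theta - gm.theta_star.theta).sum(axis=1)
        assert err.mean() < 0.1

    def test_empty_dataset_rejected(self, gm):
        cfg = TrainingRunConfig(seed=1)
        with pytest.raises(ValueError, match="empty"):
            fit_transitions_cml([], [], TransitionModel.uniform(gm.topology), cfg)


class TestJointLossAlgebra:
    def test_combined_residual_worked_example(self):
        # target 1, HMM-updated emission 0.6, network output 0.7:
        # ((1-0.6)+(1-0.7))^2 = 0.49
        from topsec.training import JointRoundState

        T = np.array([[1.0]])
        E_upd = np.array([[0.6]])
        e = np.array([[0.7]])
        state = JointRoundState(E_k=E_upd, T_k=T, error_table=(T - E_upd) + (T - e),
                                L2=float((((T - E_upd) + (T - e)) ** 2).mean()))
        assert state.error_table[0, 0] == pytest.approx(0.7)
        assert state.L2 == pytest.approx(0.49)

    def test_zero_error_when_all_agree(self):
        from topsec.training import JointRoundState

        T = np.array([[1.0, 0.0]])
        state = JointRoundState(E_k=T, T_k=T, error_table=(T - T) + (T - T), L2=0.0)
        assert state.L2 == 0.0

    def test_nonfinite_l2_rejected(self):
        from topsec.training import JointRoundState

        with pytest.raises(FloatingPointError):
            JointRoundState(E_k=np.zeros((1, 1)), T_k=np.zeros((1, 1)),
                            error_table=np.zeros((1, 1)), L2=float("nan"))


@pytest.fixture(scope="module")
def separate_model(small_corpus):
    cfg = TrainingRunConfig(seed=1, cml_max_iter=15)
    net_cfg = EmissionNetworkConfig(
        conv_layers=[(8, 3)], lstm_units=4, fc_units=(16, 8), seed=1, max_epochs=4
    )
    return train_separate(small_corpus.records, cfg, net_cfg)


class TestPipelines:
    def test_predictions_use_label_alphabet(self, separate_model, small_corpus):
        res = separate_model.predict(small_corpus.records[0].sequence)
        assert set(res.label_path) <= set("MHCE")
        assert len(res.label_path) == len(small_corpus.records[0])

    def test_bundle_roundtrip_identical_predictions(self, separate_model, small_corpus, tmp_path):
        separate_model.save(tmp_path / "model")
        from topsec.training import TrainedModel

        back = TrainedModel.load(tmp_path / "model")
        for r in small_corpus.records[:3]:
            a = separate_model.predict(r.sequence)
            b = back.predict(r.sequence)
            assert a.label_path == b.label_path
            assert a.log_score == pytest.approx(b.log_score)

    def test_joint_smoke(self, small_corpus):
        cfg = TrainingRunConfig(regime="joint", seed=1, max_outer_rounds=3)
        net_cfg = EmissionNetworkConfig(
            head="sigmoid_per_state", conv_layers=[(8, 3)], lstm_units=4, fc_units=(16, 8), seed=1
        )
        model = train_joint(small_corpus.records, cfg, net_cfg)
        l2 = model.training_log["l2_trace"]
        assert len(l2) == 3 and all(np.isfinite(l2))
        test = small_corpus.records[:5]
        q4 = q_accuracy(
            "".join(model.predict(r.sequence).label_path for r in test),
            "".join(r.labels for r in test),
        )
        assert q4 > 0.25

    def test_joint_requires_sigmoid_head(self, small_corpus):
        cfg = TrainingRunConfig(regime="joint", seed=1)
        with pytest.raises(ValueError, match="sigmoid_per_state"):
            train_joint(small_corpus.records, cfg, EmissionNetworkConfig(head="softmax_states"))
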
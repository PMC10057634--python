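"""Dynamic-programming correctness against explicit path enumeration."""

import numpy as np
import pytest

from topsec.chmm import (
    cml_loss,
    log_backward,
    log_clamped_forward,
    log_forward,
    update_transitions,
    viterbi,
)
from topsec.emission import EmissionTable
from topsec.state_model import TransitionModel

from conftest import (
    brute_force_logP,
    brute_force_viterbi,
    make_topology,
    random_instance,
    raw_model,
)


class TestForwardBackward:
    def test_certain_chain_has_zero_loss(self):
        t = make_topology(["C"])
        theta = np.zeros((3, 3))
        theta[0, 1] = 1.0
        theta[1, 1] = 0.5
        theta[1, 2] = 0.5
        # single state; adjust so the only path has probability 1
        theta[1, 1], theta[1, 2] = 0.0, 1.0
        tm = raw_model(theta, t)
        E = EmissionTable(np.ones((1, 1)))
        assert log_forward(E, tm, t) == pytest.approx(0.0, abs=1e-12)

    def test_toy_model_matches_enumeration(self, toy):
        t, tm, E, theta = toy
        expected = brute_force_logP(E, theta, t)
        assert log_forward(EmissionTable(E), tm, t) == pytest.approx(expected, rel=1e-12)
        assert log_backward(EmissionTable(E), tm, t) == pytest.approx(expected, rel=1e-12)

    def test_emission_rescaling_shifts_loss_linearly(self, toy):
        t, tm, E, _ = toy
        base = log_forward(EmissionTable(E), tm, t)
        halved = log_forward(EmissionTable(E / 2), tm, t)
        assert halved - base == pytest.approx(E.shape[0] * np.log(2), rel=1e-12)

    def test_empty_table_rejected(self, toy):
        t, tm, _, _ = toy
        with pytest.raises(ValueError):
            log_forward(EmissionTable(np.zeros((0, 2))), tm, t)

    def test_column_mismatch_rejected(self, toy):
        t, tm, _, _ = toy
        with pytest.raises(ValueError):
            log_forward(EmissionTable(np.ones((3, 5))), tm, t)

    def test_forward_equals_backward_on_random_instances(self, rng):
        for _ in range(200):
            t, tm, E = random_instance(rng, max_len=12, dense=False)
            f = log_forward(EmissionTable(E), tm, t)
            b = log_backward(EmissionTable(E), tm, t)
            assert f == pytest.approx(b, rel=1e-8, abs=1e-8)


class TestClamped:
    def test_single_consistent_path(self, toy):
        t, tm, E, theta = toy
        y = "MC"
        expected = -np.log(theta[0, 1] * E[0, 0] * theta[1, 2] * E[1, 1] * theta[2, 3])
        assert log_clamped_forward(EmissionTable(E), tm, t, y) == pytest.approx(expected, rel=1e-12)

    def test_clamped_never_below_free(self, rng):
        for _ in range(100):
            t, tm, E = random_instance(rng)
            classes = t.emitting_classes()
            y = "".join(rng.choice(classes, size=E.shape[0]))
            Lc = log_clamped_forward(EmissionTable(E), tm, t, y)
            Lf = log_forward(EmissionTable(E), tm, t)
            assert Lc >= Lf - 1e-9

    def test_matches_enumeration(self, rng):
        for _ in range(60):
            t, tm, E = random_instance(rng)
            classes = t.emitting_classes()
            y = "".join(rng.choice(classes, size=E.shape[0]))
            expected = brute_force_logP(E, tm.theta, t, labels=y)
            got = log_clamped_forward(EmissionTable(E), tm, t, y)
            if np.isinf(expected):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(expected, rel=1e-10)

    def test_infeasible_label_gives_infinity(self):
        t = make_topology(["M", "C"])
        tm = TransitionModel.uniform(t)
        E = EmissionTable(np.ones((2, 2)))
        with pytest.raises(ValueError, match="matches no emitting state"):
            log_clamped_forward(E, tm, t, "ME")

    def test_label_sum_recovers_free_probability(self, rng):
        # sum over all label strings of P(x,y) == P(x)
        import itertools

        for _ in range(15):
            t, tm, E = random_instance(rng, max_states=3, max_len=4)
            classes = sorted(set(t.emitting_classes()))
            Lf = log_forward(EmissionTable(E), tm, t)
            tot = 0.0
            for combo in itertools.product(classes, repeat=E.shape[0]):
                Lc = log_clamped_forward(EmissionTable(E), tm, t, "".join(combo))
                tot += np.exp(-Lc)
            assert -np.log(tot) == pytest.approx(Lf, rel=1e-10)


class TestCMLLoss:
    def test_zero_loss_when_all_paths_consistent(self):
        t = make_topology(["M", "M"])  # every state carries the label class
        tm = TransitionModel.uniform(t)
        E = EmissionTable(np.full((3, 2), 0.5))
        res = cml_loss(E, tm, t, "MMM")
        assert res.L == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.grad_theta, 0.0, atol=1e-12)

    def test_loss_nonnegative_fuzzed(self, rng):
        for _ in range(100):
            t, tm, E = random_instance(rng)
            y = "".join(rng.choice(t.emitting_classes(), size=E.shape[0]))
            res = cml_loss(EmissionTable(E), tm, t, y)
            assert res.L >= -1e-9
            assert res.L == pytest.approx(res.Lc - res.Lf)

    def test_grad_zero_on_disallowed_edges(self, rng):
        t, tm, E = random_instance(rng, dense=False)
        y = "".join(rng.choice(t.emitting_classes(), size=E.shape[0]))
        res = cml_loss(EmissionTable(E), tm, t, y)
        assert (res.grad_theta[~t.allowed] == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        h = 1e-5
        for _ in range(17):
            t, tm, E = random_instance(rng, max_len=5, min_len=2)
            y = "".join(rng.choice(t.emitting_classes(), size=E.shape[0]))
            res = cml_loss(EmissionTable(E), tm, t, y)

            def L_of(theta, Em):
                m = raw_model(theta, t)
                return log_clamped_forward(EmissionTable(Em), m, t, y) - log_forward(
                    EmissionTable(Em), m, t
                )

            for i, j in zip(*np.nonzero(t.allowed)):
                tp, tmn = tm.theta.copy(), tm.theta.copy()
                tp[i, j] += h
                tmn[i, j] -= h
                fd = (L_of(tp, E) - L_of(tmn, E)) / (2 * h)
                assert res.grad_theta[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)
            for p in range(E.shape[0]):
                for k in range(E.shape[1]):
                    Ep, Em_ = E.copy(), E.copy()
                    Ep[p, k] += h
                    Em_[p, k] -= h
                    fd = (L_of(tm.theta, Ep) - L_of(tm.theta, Em_)) / (2 * h)
                    assert res.grad_emissions[p, k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestViterbi:
    def test_toy_matches_enumeration(self, toy):
        t, tm, E, theta = toy
        best_path, best_p = brute_force_viterbi(E, theta, t)
        res = viterbi(EmissionTable(E), tm, t)
        assert res.state_path == best_path
        assert res.log_score == pytest.approx(np.log(best_p), rel=1e-12)
        assert res.label_path == "MC"

    def test_matches_enumeration_fuzzed(self, rng):
        for _ in range(100):
            t, tm, E = random_instance(rng, dense=False)
            res = viterbi(EmissionTable(E), tm, t)
            best_path, best_p = brute_force_viterbi(E, tm.theta, t)
            assert res.log_score == pytest.approx(np.log(best_p), rel=1e-10)
            # decoded path respects the allowed mask end to end
            full = [t.begin_id] + res.state_path + [t.end_id]
            assert all(t.allowed[a, b] for a, b in zip(full, full[1:]))

    def test_max_never_exceeds_sum(self, rng):
        for _ in range(50):
            t, tm, E = random_instance(rng)
            res = viterbi(EmissionTable(E), tm, t)
            Lf = log_forward(EmissionTable(E), tm, t)
            assert res.log_score <= -Lf + 1e-10

    def test_deterministic_chain_scores_zero(self):
        t = make_topology(["C"])
        theta = np.zeros((3, 3))
        theta[0, 1], theta[1, 2] = 1.0, 1.0
        tm = raw_model(theta, t)
        res = viterbi(EmissionTable(np.ones((1, 1))), tm, t)
        assert res.log_score == pytest.approx(0.0, abs=1e-12)
        assert res.label_path == "C"


class TestUpdateTransitions:
    def test_zero_gradient_is_identity(self, toy):
        t, tm, _, _ = toy
        tm2 = update_transitions(tm, np.zeros_like(tm.theta), 0.1)
        assert np.allclose(tm2.theta, tm.theta, atol=1e-12)

    def test_rows_stay_normalized(self, rng, toy):
        t, tm, _, _ = toy
        tm2 = update_transitions(tm, rng.normal(size=tm.theta.shape), 0.5)
        out = t.allowed.any(axis=1)
        assert np.allclose(tm2.row_sums()[out], 1.0, atol=1e-9)
        assert (tm2.theta[~t.allowed] == 0).all()

    def test_repeated_steps_decrease_loss(self, toy):
        t, tm, E, _ = toy
        y = "MC"
        losses = []
        for _ in range(50):
            res = cml_loss(EmissionTable(E), tm, t, y)
            losses.append(res.L)
            tm = update_transitions(tm, res.grad_theta, 0.05)
        assert losses[-1] < losses[0]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_nonfinite_gradient_rejected(self, toy):
        t, tm, _, _ = toy
        g = np.zeros_like(tm.theta)
        g[0, 1] = np.nan
        with pytest.raises(ValueError):
            update_transitions(tm, g, 0.1)
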
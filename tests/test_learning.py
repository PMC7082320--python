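"""Loss, error feedback, weight updates, and the training iteration."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from stdfa import (
    DEFAULT_POWER2_SET,
    TrainConfig,
    WEIGHT_FORMAT,
    bp_hidden_error,
    dfa_hidden_error,
    dfa_hidden_error_fixed,
    forward_pass,
    init_network,
    make_feedback,
    output_error,
    quantize,
    rate_loss,
    stdfa_weight_update,
    target_counts,
    train_example,
)


class TestRateLoss:
    def test_zero_at_target(self):
        y = np.array([5, 35, 5])
        assert rate_loss(y, y) == 0.0

    def test_unit_offset_on_ten_outputs(self):
        y = np.arange(10)
        assert rate_loss(y + 1, y) == pytest.approx(5.0)

    def test_matches_elementwise_sum_of_squares(self, rng):
        o = rng.integers(0, 50, size=8)
        y = rng.integers(0, 50, size=8)
        assert rate_loss(o, y) == pytest.approx(0.5 * sum((a - b) ** 2 for a, b in zip(o, y)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rate_loss(np.zeros(3), np.zeros(4))


class TestOutputError:
    def test_zero_at_target_and_scaling_in_threshold(self):
        o = np.array([10, 12, 5])
        y = np.array([10, 10, 5])
        d1 = output_error(o, y, 1.0)
        assert d1[0] == 0.0 and d1[2] == 0.0 and d1[1] == 2.0
        assert np.allclose(output_error(o, y, 2.0), d1 / 2)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            output_error(np.zeros(2), np.zeros(2), 0.0)


class TestDfaHiddenError:
    def test_zero_output_error_gives_zero(self):
        B = make_feedback((6, 3), seed=1)
        assert np.all(dfa_hidden_error(np.zeros(3), B) == 0)

    def test_single_nonzero_entry_routes_one_term(self):
        b = np.zeros((4, 3))
        b[2, 1] = 2.0
        B = make_feedback((4, 3), seed=0)
        B = replace(B, b=b, shift_exponents=np.where(b != 0, 1, 0).astype(np.int64),
                    signs=np.sign(b).astype(np.int64))
        delta_o = np.array([7.0, 3.0, -1.0])
        d = dfa_hidden_error(delta_o, B)
        assert d[2] == 6.0 and np.all(np.delete(d, 2) == 0)

    def test_shift_path_bit_identical_to_dense_float(self, rng):
        for trial in range(30):
            B = make_feedback((10, 5), seed=trial)
            delta_o = rng.normal(0, 30, size=5)
            shift = dfa_hidden_error(delta_o, B, use_shifts=True)
            dense = dfa_hidden_error(delta_o, B, use_shifts=False)
            assert np.array_equal(shift, dense)  # bit-for-bit

    def test_shift_path_bit_identical_to_dense_fixed_point(self, rng):
        for trial in range(30):
            B = make_feedback((10, 5), seed=trial + 100)
            dq = quantize(rng.normal(0, 30, size=5), WEIGHT_FORMAT)
            shift = dfa_hidden_error_fixed(dq, B, use_shifts=True)
            dense = dfa_hidden_error_fixed(dq, B, use_shifts=False)
            assert np.array_equal(shift.raw, dense.raw)

    def test_shape_mismatch_rejected(self):
        B = make_feedback((4, 3), seed=0)
        with pytest.raises(ValueError):
            dfa_hidden_error(np.zeros(4), B)


class TestWeightUpdate:
    def test_zero_delta_or_silent_synapse_gives_zero(self, rng):
        e = rng.uniform(0, 5, size=(4, 6))
        assert np.all(stdfa_weight_update(np.zeros(4), e, 0.01) == 0)
        e[:, 2] = 0.0
        dw = stdfa_weight_update(rng.normal(size=4), e, 0.01)
        assert np.all(dw[:, 2] == 0)

    def test_matches_elementwise_outer_product(self, rng):
        delta = rng.normal(size=5)
        e = rng.uniform(0, 3, size=(5, 7))
        eta = 1e-3
        dw = stdfa_weight_update(delta, e, eta)
        for i in range(5):
            for j in range(7):
                assert dw[i, j] == pytest.approx(eta * delta[i] * e[i, j])

    def test_sign_convention_decreases_weights_of_overactive_neurons(self):
        """o > y gives positive delta, so w <- w - eta*delta*e shrinks the
        weights from active (e > 0) pre-synaptic neurons."""
        delta = output_error(np.array([12]), np.array([5]), 1.0)
        e = np.array([[3.0]])
        dw = stdfa_weight_update(delta, e, 0.01)
        assert dw[0, 0] > 0  # subtracted => weight decreases


class TestBpBaselineError:
    def test_zero_delta_gives_zero(self, rng):
        out = bp_hidden_error(np.zeros(3), rng.normal(size=(3, 5)),
                              rng.uniform(0, 2, (3, 5)), rng.integers(1, 9, 5), 1.0)
        assert np.all(out == 0)

    def test_silent_neuron_convention(self, rng):
        o = np.array([4, 0, 7])
        out = bp_hidden_error(rng.normal(size=2), rng.normal(size=(2, 3)),
                              rng.uniform(0, 2, (2, 3)), o, 1.0)
        assert out[1] == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        delta = rng.normal(size=3)
        W = rng.normal(size=(3, 4))
        e = rng.uniform(0, 2, size=(3, 4))
        o = rng.integers(0, 6, size=4)
        nu = 1.5
        got = bp_hidden_error(delta, W, e, o, nu)
        for i in range(4):
            expect = 0.0
            if o[i] > 0:
                for l in range(3):
                    expect += delta[l] * W[l, i] * e[l, i] / o[i]
                expect /= nu
            assert got[i] == pytest.approx(expect)


class TestMakeFeedback:
    def test_entries_come_from_the_power2_set(self):
        B = make_feedback((50, 20), seed=3)
        assert set(np.unique(B.b)) <= set(DEFAULT_POWER2_SET)
        recon = B.signs * np.exp2(B.shift_exponents)
        assert np.array_equal(recon, B.b)

    def test_same_seed_reproduces(self):
        a = make_feedback((8, 4), seed=11)
        b = make_feedback((8, 4), seed=11)
        assert np.array_equal(a.b, b.b)

    def test_entry_frequencies_uniform_over_set(self):
        B = make_feedback((200, 70), seed=5)  # 14000 draws
        values, counts = np.unique(B.b, return_counts=True)
        assert len(values) == 7
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-4

    def test_real_variant_scale_matches_power2_rms(self):
        B = make_feedback((300, 100), variant="real-uniform", seed=9)
        rms_real = np.sqrt(np.mean(B.b**2))
        rms_set = np.sqrt(np.mean(np.square(DEFAULT_POWER2_SET)))
        assert rms_real == pytest.approx(rms_set, rel=0.05)

    def test_invalid_value_set_rejected(self):
        with pytest.raises(ValueError):
            make_feedback((3, 3), value_set=(3, -5), seed=0)
        with pytest.raises(ValueError):
            make_feedback((3, 3), value_set=(), seed=0)


class TestTargetCounts:
    def test_hi_lo_assignment_scaled_to_horizon(self):
        y = target_counts(1, 3, 100)
        assert list(y) == [5, 35, 5]
        y200 = target_counts(1, 3, 200)
        assert list(y200) == [10, 70, 10]

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            target_counts(3, 3, 100)


class TestTrainExample:
    def _fire_matching_net(self, rng):
        """Net plus input raster, and the y that equals its actual counts."""
        net = init_network((8, 6, 3), seed=4)
        raster = rng.random((8, 100)) < 0.25
        return net, raster

    def test_zero_error_is_a_fixpoint(self, rng):
        """When counts already equal targets: zero loss, zero deltas, and
        bit-identical weights after the update step."""
        net, raster = self._fire_matching_net(rng)
        counts = forward_pass(net, raster).output_counts
        cfg = TrainConfig(rule="stdfa2", hi=int(counts.max()) + 1, lo=0)
        # craft targets == counts by monkey-level config: use output_error directly
        delta = output_error(counts, counts, 1.0)
        assert np.all(delta == 0)
        before = [w.copy() for w in net.weights]
        for k, w in enumerate(net.weights):
            dw = stdfa_weight_update(
                dfa_hidden_error(delta, net.feedback[0]) if k == 0 else delta,
                forward_pass(net, raster).spsp[k],
                cfg.eta,
            )
            assert np.all(dw == 0)
        for b, w in zip(before, net.weights):
            assert np.array_equal(b, w)

    def test_hidden_error_locality_under_weight_perturbation(self, rng):
        """delta_k depends only on delta_o and B_k: perturbing the *other*
        hidden layer's weights leaves it unchanged (given the same output
        error)."""
        net = init_network((10, 8, 8, 3), seed=7)
        delta_o = rng.normal(0, 10, size=3)
        d1 = dfa_hidden_error(delta_o, net.feedback[0])
        d2 = dfa_hidden_error(delta_o, net.feedback[1])
        net.weights[1] = net.weights[1] + rng.normal(0, 1, net.weights[1].shape)
        assert np.array_equal(dfa_hidden_error(delta_o, net.feedback[0]), d1)
        net.weights[0] = net.weights[0] + rng.normal(0, 1, net.weights[0].shape)
        assert np.array_equal(dfa_hidden_error(delta_o, net.feedback[1]), d2)

    def test_hidden_updates_commute_across_layers(self, rng):
        """Computing the two hidden layers' updates in either order yields
        identical weight changes (logically concurrent DFA)."""
        raster = rng.random((10, 60)) < 0.25
        cfg = TrainConfig(rule="stdfa2", eta=1e-4)
        nets = [init_network((10, 8, 8, 3), seed=13) for _ in range(2)]
        train_example(nets[0], raster, 1, cfg)
        train_example(nets[1], raster, 1, cfg)
        for a, b in zip(nets[0].weights, nets[1].weights):
            assert np.array_equal(a, b)

    def test_repeated_training_on_one_pattern_descends(self, rng):
        net = init_network((10, 8, 3), seed=21)
        raster = rng.random((10, 100)) < 0.25
        cfg = TrainConfig(rule="stdfa2", eta=1e-5)
        losses = [train_example(net, raster, 0, cfg).loss for _ in range(30)]
        assert losses[-1] < losses[0]
        # trend is downward even if single steps fluctuate
        assert np.mean(losses[-5:]) <= np.mean(losses[:5])

    def test_frozen_rule_changes_nothing(self, rng):
        net = init_network((8, 6, 3), seed=2)
        before = [w.copy() for w in net.weights]
        train_example(net, rng.random((8, 50)) < 0.3, 1, TrainConfig(rule="frozen"))
        for b, w in zip(before, net.weights):
            assert np.array_equal(b, w)

    def test_quantized_updates_stay_on_weight_lattice(self, rng):
        net = init_network((8, 6, 3), seed=3)
        cfg = TrainConfig(rule="stdfa2", quantize=True, eta=1e-4)
        train_example(net, rng.random((8, 50)) < 0.3, 0, cfg)
        for w in net.weights:
            raw = w / WEIGHT_FORMAT.resolution
            assert np.allclose(raw, np.round(raw))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(rule="adam")
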
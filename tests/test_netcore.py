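"""Network dynamics, loss, BPTT gradients and weight persistence."""

import numpy as np
import pytest

from conftest import random_toy_network
from triread.errors import ConfigurationError, NumericError
from triread.netcore import (NetworkTopology, TrialSpec, apply_update,
                             bptt_gradients, forward_trial, init_network,
                             load_weights, save_weights, train_step,
                             trial_loss)


def fd_gradient(ws, trial, indices, eps=1e-5, bias=False):
    """Central finite differences on sampled parameters."""
    arr = ws.b if bias else ws.w
    out = []
    for k in indices:
        arr[k] += eps
        lp = trial_loss(forward_trial(ws, trial), trial)
        arr[k] -= 2 * eps
        lm = trial_loss(forward_trial(ws, trial), trial)
        arr[k] += eps
        out.append((lp - lm) / (2 * eps))
    return np.array(out)


class TestForward:
    def test_zero_weights_rest_at_half(self, tiny_topology):
        ws = init_network(tiny_topology, 0.0, seed=0, bias_init=0.0,
                          dtype=np.float64)
        trial = TrialSpec(clamps=[("inp", np.ones(3), 4)], timesteps=4)
        tr = forward_trial(ws, trial)
        for layer in ("hid", "out", "clean"):
            assert np.allclose(tr[layer][1:], 0.5)

    def test_clamped_layer_holds_pattern(self, tiny_topology):
        ws = init_network(tiny_topology, 0.3, seed=1, dtype=np.float64)
        pat = np.array([1.0, 0.0, 1.0])
        tr = forward_trial(ws, TrialSpec(clamps=[("inp", pat, 3)],
                                         timesteps=5))
        assert np.array_equal(tr["inp"][:4], np.tile(pat, (4, 1)))
        # input layer carries no incoming connections: it keeps its last
        # state after the clamp ends
        assert np.array_equal(tr["inp"][4:], np.tile(pat, (2, 1)))

    def test_two_unit_chain_matches_hand_iteration(self):
        topo = NetworkTopology(layers=(("a", 1), ("b", 1)),
                               connections=(("a", "b"),))
        ws = init_network(topo, 0.0, seed=0, bias_init=0.0,
                          dtype=np.float64)
        ws["a->b"][0, 0] = 1.0
        tr = forward_trial(ws, TrialSpec(clamps=[("a", np.ones(1), 3)],
                                         timesteps=3))

        def logistic(x):
            return 1.0 / (1.0 + np.exp(-x))

        # b starts at rest 0.5; each step sees a(t-1) = 1 through w = 1
        assert tr["b"][1, 0] == pytest.approx(logistic(1.0))
        assert tr["b"][2, 0] == pytest.approx(logistic(1.0))
        assert tr["b"][0, 0] == 0.5

    def test_nan_weight_raises_numeric_error(self, tiny_topology):
        ws = init_network(tiny_topology, 0.3, seed=2, dtype=np.float64)
        ws["inp->hid"][0, 0] = np.nan
        with pytest.raises(NumericError, match="hid"):
            forward_trial(ws, TrialSpec(clamps=[("inp", np.ones(3), 2)],
                                        timesteps=2))


class TestLoss:
    def _trial(self, target, window=(2, 3), criterion="ce"):
        return TrialSpec(clamps=[("inp", np.array([1.0, 0.0, 1.0]), 3)],
                         timesteps=3, target_layer="out", target=target,
                         window=window, criterion=criterion)

    def test_exact_binary_output_gives_zero_loss(self, tiny_topology):
        ws = init_network(tiny_topology, 0.0, seed=0, bias_init=0.0,
                          dtype=np.float64)
        # drive the output units hard on: activation saturates at 1 and
        # the clipped CE against an all-ones target vanishes
        ws.bias("out")[:] = 500.0
        tr = forward_trial(ws, self._trial(np.ones(3)))
        assert trial_loss(tr, self._trial(np.ones(3))) == \
            pytest.approx(0.0, abs=1e-4)

    def test_single_unit_half_activation_is_ln2(self):
        topo = NetworkTopology(layers=(("a", 1), ("b", 1)),
                               connections=(("a", "b"),))
        ws = init_network(topo, 0.0, seed=0, bias_init=0.0,
                          dtype=np.float64)
        trial = TrialSpec(clamps=[("a", np.ones(1), 1)], timesteps=1,
                          target_layer="b", target=np.ones(1),
                          window=(1, 1))
        assert trial_loss(forward_trial(ws, trial), trial) == \
            pytest.approx(np.log(2))

    def test_doubling_window_doubles_loss_on_constant_trace(
            self, tiny_topology):
        ws = init_network(tiny_topology, 0.0, seed=0, bias_init=0.0,
                          dtype=np.float64)
        tgt = np.array([1.0, 0.0, 1.0])
        t1 = self._trial(tgt, window=(3, 3))
        t2 = self._trial(tgt, window=(2, 3))
        tr = forward_trial(ws, t2)
        assert trial_loss(tr, t2) == pytest.approx(2 * trial_loss(tr, t1))

    def test_sse_criterion(self, tiny_topology):
        ws = init_network(tiny_topology, 0.0, seed=0, bias_init=0.0,
                          dtype=np.float64)
        tgt = np.ones(3)
        trial = self._trial(tgt, window=(3, 3), criterion="sse")
        # constant 0.5 output vs all-ones target: 3 * 0.25
        assert trial_loss(forward_trial(ws, trial), trial) == \
            pytest.approx(0.75)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(12):
            topo, ws = random_toy_network(rng)
            in_layer = topo.input_layers[0]
            others = [n for n, _ in topo.layers if n != in_layer]
            tgt_layer = others[int(rng.integers(len(others)))]
            sizes = topo.layer_sizes
            T = int(rng.integers(2, 7))
            trial = TrialSpec(
                clamps=[(in_layer,
                         rng.random(sizes[in_layer]).round(), T)],
                timesteps=T, target_layer=tgt_layer,
                target=rng.random(sizes[tgt_layer]).round(),
                window=(max(1, T - 1), T),
                criterion="sse" if rng.random() < 0.3 else "ce")
            g = bptt_gradients(ws, trial)
            idx = rng.choice(len(ws.w), size=min(20, len(ws.w)),
                             replace=False)
            fd = fd_gradient(ws, trial, idx)
            denom = np.maximum(np.abs(fd) + np.abs(g.gw[idx]), 1e-6)
            worst = max(worst, float(np.max(np.abs(fd - g.gw[idx])
                                            / denom)))
            bidx = rng.choice(len(ws.b), size=min(8, len(ws.b)),
                              replace=False)
            fdb = fd_gradient(ws, trial, bidx, bias=True)
            denomb = np.maximum(np.abs(fdb) + np.abs(g.gb[bidx]), 1e-6)
            worst = max(worst, float(np.max(np.abs(fdb - g.gb[bidx])
                                            / denomb)))
        assert worst < 1e-4

    def test_frozen_group_gets_zero_gradient(self, tiny_topology):
        ws = init_network(tiny_topology, 0.4, seed=3, dtype=np.float64)
        ws.set_trainable({"hid->out"}, {"out"})
        trial = TrialSpec(clamps=[("inp", np.ones(3), 3)], timesteps=3,
                          target_layer="out", target=np.ones(3),
                          window=(2, 3))
        g = bptt_gradients(ws, trial)
        assert not g["inp->hid"].any()
        assert not g.bias("hid").any()
        assert g["hid->out"].any()
        assert g.bias("out").any()

    def test_empty_error_window_gives_zero_gradients(self, tiny_topology):
        ws = init_network(tiny_topology, 0.4, seed=4, dtype=np.float64)
        g = bptt_gradients(ws, TrialSpec(clamps=[("inp", np.ones(3), 3)],
                                         timesteps=3))
        assert not g.gw.any() and not g.gb.any()


class TestUpdate:
    def _trial(self):
        return TrialSpec(clamps=[("inp", np.array([1.0, 0.0, 1.0]), 3)],
                         timesteps=3, target_layer="out",
                         target=np.array([1.0, 0.0, 1.0]), window=(2, 3))

    def test_zero_learning_rate_leaves_weights(self, tiny_topology):
        ws = init_network(tiny_topology, 0.4, seed=5, dtype=np.float64)
        g = bptt_gradients(ws, self._trial())
        out = apply_update(ws, g, 0.0)
        assert out == ws

    def test_one_step_reduces_loss(self, tiny_topology):
        ws = init_network(tiny_topology, 0.4, seed=6, dtype=np.float64)
        trial = self._trial()
        before = trial_loss(forward_trial(ws, trial), trial)
        out = apply_update(ws, bptt_gradients(ws, trial), 0.05)
        after = trial_loss(forward_trial(out, trial), trial)
        assert after < before

    def test_frozen_group_bit_identical_after_update(self, tiny_topology):
        ws = init_network(tiny_topology, 0.4, seed=7, dtype=np.float64)
        ws.set_trainable({"hid->out"}, {"out"})
        frozen = ws["inp->hid"].copy()
        train_step(ws, self._trial(), 0.05)
        assert np.array_equal(ws["inp->hid"], frozen)
        assert not np.array_equal(
            ws["hid->out"],
            init_network(tiny_topology, 0.4, seed=7,
                         dtype=np.float64)["hid->out"])


class TestInitAndIO:
    def test_same_seed_identical_different_seed_differs(self,
                                                        tiny_topology):
        a = init_network(tiny_topology, 0.1, seed=0)
        b = init_network(tiny_topology, 0.1, seed=0)
        c = init_network(tiny_topology, 0.1, seed=1)
        assert a == b
        assert a != c

    def test_zero_init_range(self, tiny_topology):
        ws = init_network(tiny_topology, 0.0, seed=0)
        assert not ws.w.any()

    def test_bias_init_negative_on_receiving_layers(self, tiny_topology):
        ws = init_network(tiny_topology, 0.1, seed=0)
        assert np.all(ws.bias("hid") == -1.0)
        assert np.all(ws.bias("inp") == 0.0)  # input layer: no bias in use

    def test_save_load_roundtrip(self, tiny_topology, tmp_path):
        ws = init_network(tiny_topology, 0.2, seed=8, dtype=np.float64)
        ws.meta["trial_count"] = 1234
        ws.meta["phase"] = "oral"
        p = tmp_path / "w.npz"
        save_weights(ws, p)
        back = load_weights(p)
        assert back == ws
        assert back.meta["trial_count"] == 1234
        assert back.meta["phase"] == "oral"

    def test_load_with_incompatible_topology_raises(self, tiny_topology,
                                                    tmp_path):
        ws = init_network(tiny_topology, 0.2, seed=9)
        p = tmp_path / "w.npz"
        save_weights(ws, p)
        other = NetworkTopology(layers=(("inp", 3), ("hid", 5),
                                        ("out", 3), ("clean", 2)),
                                connections=tiny_topology.connections)
        with pytest.raises(ConfigurationError):
            load_weights(p, topology=other)

    def test_train_determinism(self, tiny_topology):
        results = []
        for _ in range(2):
            ws = init_network(tiny_topology, 0.3, seed=10,
                              dtype=np.float64)
            rng = np.random.default_rng(0)
            for _ in range(50):
                pat = rng.random(3).round()
                trial = TrialSpec(clamps=[("inp", pat, 3)], timesteps=3,
                                  target_layer="out", target=pat,
                                  window=(2, 3))
                train_step(ws, trial, 0.05)
            results.append(ws.w.copy())
        assert np.array_equal(results[0], results[1])
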
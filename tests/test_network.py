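"""Hub-and-spoke dynamics: forward pass, clamps, BPTT gradients, persistence."""

import numpy as np
import pytest

from lexhub.network import (
    Gradients,
    NetworkConfig,
    Trial,
    apply_update,
    bptt_gradients,
    init_network,
    load_network,
    run_trial,
    save_network,
    trial_loss,
)


def random_trial(cfg, rng, T=5, clamp_sem=False, clamp_eye=False):
    """A toy trial with binary targets and optional clamps."""
    sem_clamp_on = np.zeros(T, dtype=bool)
    eye_clamp_on = np.zeros(T, dtype=bool)
    sem_mask = np.zeros(T, dtype=bool)
    eye_mask = np.zeros(T, dtype=bool)
    sem_mask[2:] = True
    eye_mask[1:] = True
    if clamp_sem:
        sem_clamp_on[:2] = True
    if clamp_eye:
        eye_clamp_on[:] = True
        eye_mask[:] = False
    return Trial(
        T=T,
        vision=rng.random((T, cfg.n_vis)),
        phonology=rng.random((T, cfg.n_phon)),
        sem_clamp=rng.random(cfg.n_sem) if clamp_sem else None,
        sem_clamp_on=sem_clamp_on,
        eye_clamp=rng.random(cfg.n_eye) if clamp_eye else None,
        eye_clamp_on=eye_clamp_on,
        sem_target=rng.integers(0, 2, cfg.n_sem).astype(float),
        sem_mask=sem_mask,
        eye_target=rng.integers(0, 2, cfg.n_eye).astype(float),
        eye_mask=eye_mask,
    )


def finite_difference(net, trial, eps=1e-5):
    """Central-difference gradient of the masked trial loss."""
    out = {}
    for name in ("W_in", "b_hub", "W_out", "b_out"):
        W = getattr(net, name)
        num = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = W[i]
            W[i] = old + eps
            fp = trial_loss(run_trial(net, trial), trial, net)[0]
            W[i] = old - eps
            fm = trial_loss(run_trial(net, trial), trial, net)[0]
            W[i] = old
            num[i] = (fp - fm) / (2 * eps)
        out[name] = num
    return out


class TestInit:
    def test_range_and_determinism(self):
        net1 = init_network(seed=5)
        net2 = init_network(seed=5)
        for name in ("W_in", "b_hub", "W_out", "b_out"):
            a, b = getattr(net1, name), getattr(net2, name)
            assert np.abs(a).max() <= 0.1
            assert np.array_equal(a, b)

    def test_mean_matches_uniform(self):
        net = init_network(seed=6)
        entries = np.concatenate(
            [net.W_in.ravel(), net.b_hub, net.W_out.ravel(), net.b_out]
        )
        se = (0.2 / np.sqrt(12)) / np.sqrt(entries.size)
        assert abs(entries.mean()) < 3 * se

    def test_block_views_cover_input_matrix(self):
        net = init_network(seed=0)
        total = sum(
            b.shape[0]
            for b in (
                net.W_vision_hub,
                net.W_phon_hub,
                net.W_sem_hub,
                net.W_eye_hub,
                net.W_hub_hub,
            )
        )
        assert total == net.W_in.shape[0]
        assert net.W_hub_sem.shape == (net.config.n_hub, net.config.n_sem)
        assert net.W_hub_eye.shape == (net.config.n_hub, net.config.n_eye)


class TestForward:
    def test_zero_weights_give_half_activation(self, toy_network_config):
        cfg = toy_network_config
        net = init_network(cfg, seed=0)
        for name in ("W_in", "b_hub", "W_out", "b_out"):
            getattr(net, name)[:] = 0.0
        rng = np.random.default_rng(0)
        trial = random_trial(cfg, rng)
        hist = run_trial(net, trial)
        assert np.allclose(hist.hub[1:], 0.5)
        assert np.allclose(hist.out_computed[1:], 0.5)

    def test_clamp_dominates_weights(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(1)
        net = init_network(cfg, seed=1)
        net.W_out[:] = rng.normal(size=net.W_out.shape)  # large random weights
        clamp = np.array([1.0, 0.0])
        trial = random_trial(cfg, rng, clamp_eye=True)
        trial.eye_clamp = clamp
        hist = run_trial(net, trial)
        assert np.array_equal(hist.eye, np.tile(clamp, (trial.T, 1)))

    def test_history_lengths(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(2)
        net = init_network(cfg, seed=2)
        for T in (15, 30):
            hist = run_trial(net, random_trial(cfg, rng, T=T))
            assert hist.T == T

    def test_purity(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(3)
        net = init_network(cfg, seed=3)
        trial = random_trial(cfg, rng)
        h1 = run_trial(net, trial)
        h2 = run_trial(net, trial)
        assert np.array_equal(h1.hub, h2.hub)

    def test_free_activations_stay_in_unit_interval(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(4)
        for seed in range(10):
            net = init_network(cfg, seed=seed)
            net.W_in *= 50  # exaggerate weights; sigmoid still bounds output
            hist = run_trial(net, random_trial(cfg, rng, T=8))
            for arr in (hist.hub, hist.out_computed):
                assert (arr > 0).all() and (arr < 1).all()

    def test_simultaneous_clamp_and_target_rejected(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(5)
        trial = random_trial(cfg, rng, clamp_sem=True)
        with pytest.raises(ValueError):
            Trial(
                T=trial.T,
                vision=trial.vision,
                phonology=trial.phonology,
                sem_clamp=trial.sem_clamp,
                sem_clamp_on=np.ones(trial.T, dtype=bool),
                sem_target=trial.sem_target,
                sem_mask=trial.sem_mask,
            )


class TestLoss:
    def test_no_mask_no_loss(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(6)
        net = init_network(cfg, seed=6)
        trial = random_trial(cfg, rng)
        trial.sem_mask[:] = False
        trial.eye_mask[:] = False
        loss, _ = trial_loss(run_trial(net, trial), trial, net)
        assert loss == 0.0

    def test_half_activation_binary_target_is_ln2(self, toy_network_config):
        import dataclasses

        cfg = dataclasses.replace(toy_network_config, loss="cross_entropy")
        net = init_network(cfg, seed=7)
        for name in ("W_in", "b_hub", "W_out", "b_out"):
            getattr(net, name)[:] = 0.0  # every output sits at 0.5
        T = 3
        trial = Trial(
            T=T,
            vision=np.zeros((T, cfg.n_vis)),
            phonology=np.zeros((T, cfg.n_phon)),
            eye_target=np.array([1.0, 0.0])[: cfg.n_eye],
            eye_mask=np.array([False, False, True]),
        )
        loss, breakdown = trial_loss(run_trial(net, trial), trial, net)
        # each of n_eye units at 0.5 contributes ln 2 at the single masked tick
        assert loss == pytest.approx(cfg.n_eye * np.log(2), rel=1e-9)
        assert breakdown["eye"][2] == pytest.approx(loss)
        assert breakdown["semantics"].sum() == 0.0


class TestGradients:
    @pytest.mark.parametrize("loss_kind", ["cross_entropy", "sse"])
    @pytest.mark.parametrize("teacher_force", [True, False])
    @pytest.mark.parametrize("clamp", [(False, False), (True, False), (False, True)])
    def test_matches_finite_differences(
        self, toy_network_config, loss_kind, teacher_force, clamp
    ):
        import dataclasses

        cfg = dataclasses.replace(toy_network_config, loss=loss_kind)
        rng = np.random.default_rng(8)
        net = init_network(cfg, seed=8)
        trial = random_trial(cfg, rng, clamp_sem=clamp[0], clamp_eye=clamp[1])
        trial.teacher_force = teacher_force
        grads, _ = bptt_gradients(net, trial)
        num = finite_difference(net, trial)
        for name in ("W_in", "b_hub", "W_out", "b_out"):
            analytic = getattr(grads, name)
            denom = np.maximum(np.abs(num[name]), 1e-4)
            rel = np.abs(analytic - num[name]) / denom
            assert rel.max() < 1e-5, f"{name}: max rel err {rel.max():.2e}"

    def test_no_mask_zero_gradient(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(9)
        net = init_network(cfg, seed=9)
        trial = random_trial(cfg, rng)
        trial.sem_mask[:] = False
        trial.eye_mask[:] = False
        grads, loss = bptt_gradients(net, trial)
        assert loss == 0.0
        for name in ("W_in", "b_hub", "W_out", "b_out"):
            assert np.all(getattr(grads, name) == 0.0)

    def test_sgd_descends_on_fixed_trial(self, toy_network_config):
        cfg = toy_network_config
        rng = np.random.default_rng(10)
        net = init_network(cfg, seed=10)
        trial = random_trial(cfg, rng)
        losses = []
        for _ in range(30):
            grads, loss = bptt_gradients(net, trial)
            losses.append(loss)
            apply_update(net, grads, rate=0.05)
        assert losses[-1] < losses[0]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


class TestUpdate:
    def test_zero_gradient_and_zero_rate_noop(self, toy_network_config):
        net = init_network(toy_network_config, seed=11)
        before = net.W_in.copy()
        zeros = Gradients(
            W_in=np.zeros_like(net.W_in),
            b_hub=np.zeros_like(net.b_hub),
            W_out=np.zeros_like(net.W_out),
            b_out=np.zeros_like(net.b_out),
        )
        apply_update(net, zeros, rate=0.05)
        assert np.array_equal(net.W_in, before)
        grads, _ = bptt_gradients(
            net, random_trial(toy_network_config, np.random.default_rng(11))
        )
        apply_update(net, grads, rate=0.0)
        assert np.array_equal(net.W_in, before)

    def test_single_step_arithmetic(self, toy_network_config):
        net = init_network(toy_network_config, seed=12)
        net.W_in[0, 0] = 0.0
        g = Gradients(
            W_in=np.zeros_like(net.W_in),
            b_hub=np.zeros_like(net.b_hub),
            W_out=np.zeros_like(net.W_out),
            b_out=np.zeros_like(net.b_out),
        )
        g.W_in[0, 0] = 2.0
        apply_update(net, g, rate=0.05)
        assert net.W_in[0, 0] == pytest.approx(-0.1)


class TestPersistence:
    def test_round_trip(self, toy_network_config, tmp_path):
        net = init_network(toy_network_config, seed=13)
        net.meta["regime"] = "noisy"
        path = tmp_path / "net.npz"
        save_network(net, path)
        back = load_network(path)
        for name in ("W_in", "b_hub", "W_out", "b_out"):
            assert np.array_equal(getattr(back, name), getattr(net, name))
        assert back.config == net.config
        assert back.meta["regime"] == "noisy"

    def test_missing_and_truncated_files_error(self, toy_network_config, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_network(tmp_path / "absent.npz")
        net = init_network(toy_network_config, seed=14)
        path = tmp_path / "net.npz"
        save_network(net, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(IOError):
            load_network(path)
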
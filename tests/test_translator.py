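import numpy as np
import pytest

from vtstain import synthetic, tiling, translator
from vtstain.translator import (Critic, Generator, TrainConfig, TranslatorState,
                                adversarial_loss, cycle_loss, from_unit,
                                load_checkpoint, save_checkpoint, to_unit, train,
                                translate_tile)


def brute_force_lsgan(critic, real, fake):
    """Pixel-by-pixel loop over the least-squares GAN terms."""
    s_real = critic(real)
    s_fake = critic(fake)
    d_sum_r = d_sum_f = g_sum = 0.0
    n = 0
    for idx in np.ndindex(s_real.shape):
        d_sum_r += (s_real[idx] - 1.0) ** 2
        d_sum_f += s_fake[idx] ** 2
        g_sum += (s_fake[idx] - 1.0) ** 2
        n += 1
    return {"discriminator": d_sum_r / n + d_sum_f / n, "generator": g_sum / n}


def brute_force_cycle(g_ab, g_ba, a, b):
    rec_a = g_ba(g_ab(a))
    rec_b = g_ab(g_ba(b))
    total_a = sum(abs(rec_a[idx] - a[idx]) for idx in np.ndindex(a.shape))
    total_b = sum(abs(rec_b[idx] - b[idx]) for idx in np.ndindex(b.shape))
    return total_a / a.size + total_b / b.size


class _ConstantCritic:
    def __init__(self, value):
        self.value = value

    def __call__(self, x):
        return np.full(x.shape[:-1], self.value)


class TestLosses:
    def test_perfect_discriminator_zero_loss(self, rng):
        real = rng.uniform(-1, 1, (2, 4, 4, 3))
        fake = rng.uniform(-1, 1, (2, 4, 4, 3))

        class Perfect:
            def __call__(self, x):
                return np.ones(x.shape[:-1]) if x is real else np.zeros(x.shape[:-1])

        out = adversarial_loss(Perfect(), real, fake)
        assert out["discriminator"] == 0.0

    def test_half_output_closed_form(self, rng):
        batch = rng.uniform(-1, 1, (2, 4, 4, 3))
        out = adversarial_loss(_ConstantCritic(0.5), batch, batch)
        assert out["discriminator"] == pytest.approx(0.5)
        assert out["generator"] == pytest.approx(0.25)

    def test_adversarial_matches_brute_force(self, rng):
        critic = Critic(hidden=8, rng=rng)
        real = rng.uniform(-1, 1, (4, 8, 8, 3))
        fake = rng.uniform(-1, 1, (4, 8, 8, 3))
        fast = adversarial_loss(critic, real, fake)
        slow = brute_force_lsgan(critic, real, fake)
        assert fast["discriminator"] == pytest.approx(slow["discriminator"], abs=1e-6)
        assert fast["generator"] == pytest.approx(slow["generator"], abs=1e-6)

    def test_cycle_identity_generators_zero(self, rng):
        g_ab = Generator(identity=True)
        g_ba = Generator(identity=True)
        a = rng.uniform(-1, 1, (2, 8, 8, 3))
        b = rng.uniform(-1, 1, (2, 8, 8, 3))
        assert cycle_loss(g_ab, g_ba, a, b) == 0.0

    def test_cycle_exact_inverse_pair_zero(self, rng):
        class Shift:
            def __init__(self, delta):
                self.delta = delta

            def __call__(self, x):
                return x + self.delta

        a = rng.uniform(-0.25, 0.25, (2, 4, 4, 3))
        b = rng.uniform(-0.25, 0.25, (2, 4, 4, 3))
        assert cycle_loss(Shift(0.5), Shift(-0.5), a, b) == pytest.approx(0.0)

    def test_cycle_matches_brute_force(self, rng):
        g_ab = Generator(hidden=8, rng=rng)
        g_ba = Generator(hidden=8, rng=rng)
        a = rng.uniform(-1, 1, (2, 6, 6, 3))
        b = rng.uniform(-1, 1, (2, 6, 6, 3))
        assert cycle_loss(g_ab, g_ba, a, b) == pytest.approx(
            brute_force_cycle(g_ab, g_ba, a, b), abs=1e-6)

    def test_nan_activations_abort(self, rng):
        batch = rng.uniform(-1, 1, (1, 4, 4, 3))
        bad = batch.copy()
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            adversarial_loss(Critic(hidden=4, rng=rng), batch, bad)


class TestGradients:
    def test_generator_gradients_match_finite_differences(self, rng):
        """Hand-derived backprop agrees with central finite differences."""
        gen = Generator(hidden=4, rng=rng)
        x = rng.uniform(-1, 1, (1, 3, 3, 3))
        target = rng.uniform(-1, 1, (1, 3, 3, 3))

        def loss_of(params):
            gen.mlp.set_params(params)
            out, _ = gen.forward(x)
            return float(np.mean((out - target) ** 2))

        base = {k: v.copy() for k, v in gen.mlp.params().items()}
        out, cache = gen.forward(x)
        grad_out = 2 * (out - target) / out.size
        grads, _ = gen.backward(cache, grad_out)
        eps = 1e-6
        for name in base:
            flat_param = base[name]
            it = np.nditer(flat_param, flags=["multi_index"])
            for _ in range(min(flat_param.size, 5)):
                idx = it.multi_index
                up = {k: v.copy() for k, v in base.items()}
                dn = {k: v.copy() for k, v in base.items()}
                up[name][idx] += eps
                dn[name][idx] -= eps
                num = (loss_of(up) - loss_of(dn)) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
                it.iternext()
        gen.mlp.set_params(base)


class TestTranslateTile:
    def _identity_state(self):
        g = Generator(identity=True)
        d = Critic(hidden=16)
        p = g.mlp.params()
        return TranslatorState({k: v.copy() for k, v in p.items()},
                               {k: v.copy() for k, v in p.items()},
                               d.mlp.params(), d.mlp.params(), 0)

    def test_identity_initialized_passthrough(self, rng):
        tile = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        out = translate_tile(self._identity_state(), tile)
        assert np.array_equal(out, tile)

    def test_translation_deterministic(self, stain_pair, rng):
        he, _, _ = stain_pair
        state = self._identity_state()
        tile = he.pixels[:64, :64]
        assert np.array_equal(translate_tile(state, tile),
                              translate_tile(state, tile))

    def test_unit_roundtrip_exact(self, rng):
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        assert np.array_equal(from_unit(to_unit(tile)), tile)


class TestTraining:
    def _toy_tiles(self, seed):
        spec = synthetic.SyntheticSlideSpec(seed=seed, dims=(256, 256), true_stage=3)
        he, tri, key = synthetic.make_stain_pair(spec)
        ta, _ = tiling.extract_training_tiles(he, 64, max_white=1.0)
        tb, _ = tiling.extract_training_tiles(tri, 64, max_white=1.0)
        return ta, tb, key

    def test_zero_iterations_returns_initial_state(self):
        ta, tb, _ = self._toy_tiles(1)
        cfg = TrainConfig(max_iterations=0, checkpoint_every=1, crop_size=32)
        ckpts, log = train(ta, tb, cfg)
        assert len(ckpts) == 1 and ckpts[0].iteration == 0 and log == []

    def test_checkpoint_cadence(self):
        ta, tb, _ = self._toy_tiles(1)
        cfg = TrainConfig(max_iterations=10, checkpoint_every=5, crop_size=32)
        ckpts, _ = train(ta, tb, cfg)
        assert [c.iteration for c in ckpts] == [0, 5, 10]

    def test_training_determinism(self):
        ta, tb, _ = self._toy_tiles(2)
        cfg = TrainConfig(max_iterations=20, checkpoint_every=20, crop_size=32,
                          rng_seed=5)
        c1, _ = train(ta, tb, cfg)
        c2, _ = train(ta, tb, cfg)
        for s1, s2 in zip(c1, c2):
            for k in s1.g_ab:
                assert np.array_equal(s1.g_ab[k], s2.g_ab[k])
                assert np.array_equal(s1.d_a[k], s2.d_a[k])

    def test_empty_tile_set_rejected(self):
        ta, _, _ = self._toy_tiles(1)
        with pytest.raises(ValueError, match="nonempty"):
            train(ta, [], TrainConfig(max_iterations=1, checkpoint_every=1, crop_size=32))

    def test_toy_convergence_and_translation(self):
        """Cycle loss drops and the trained generator beats the untranslated
        input against the known palette-map ground truth."""
        ta, tb, _ = self._toy_tiles(3)
        cfg = TrainConfig(max_iterations=300, checkpoint_every=300, crop_size=32,
                          rng_seed=0, learning_rate=3e-3)
        ckpts, log = train(ta, tb, cfg)
        assert log[-1]["loss_cycle"] < log[0]["loss_cycle"]
        heldout, _, key = synthetic.make_stain_pair(
            synthetic.SyntheticSlideSpec(seed=77, dims=(128, 128), true_stage=3))
        truth = synthetic.apply_transform_key(key, heldout.pixels)
        out = translate_tile(ckpts[-1], heldout.pixels)
        err_translated = np.abs(out.astype(float) - truth.astype(float)).mean()
        err_raw = np.abs(heldout.pixels.astype(float) - truth.astype(float)).mean()
        assert err_translated < err_raw


def test_checkpoint_roundtrip(tmp_path, rng):
    gen = Generator(hidden=8, rng=rng)
    d = Critic(hidden=8, rng=rng)
    state = TranslatorState(gen.mlp.params(), gen.mlp.params(),
                            d.mlp.params(), d.mlp.params(), 42)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(state, path, config=TrainConfig(max_iterations=10,
                                                    checkpoint_every=5))
    loaded = load_checkpoint(path)
    assert loaded.iteration == 42
    for k in state.g_ab:
        assert np.array_equal(loaded.g_ab[k], state.g_ab[k])
    assert path.with_suffix(".json").exists()
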
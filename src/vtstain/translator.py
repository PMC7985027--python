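"""Unpaired two-domain stain translator (CycleGAN objective) at desk scale.

The objective is the standard unpaired-translation triple — least-squares
adversarial loss, cycle-consistency L1, and identity L1 — trained with
alternating discriminator/generator Adam steps on randomly cropped, seeded
batches, with periodic checkpoints.

The networks are deliberately tiny so the objective is exercisable on a single
CPU core: the generators are per-pixel residual colour maps (a 1x1-convolution
residual block, identity at initialization) and the discriminators are
per-pixel colour critics.  For the synthetic stain pairs this package studies,
where the two domains differ by an invertible palette map, this capacity is
sufficient for the objective to drive the generators to the true transform;
gradients are derived by hand, so there is no autodiff dependency.

Images cross the module boundary as 8-bit RGB and live in [-1, 1] float
internally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_LEAK = 0.2


def to_unit(tile: np.ndarray) -> np.ndarray:
    """uint8 RGB -> float in [-1, 1]."""
    return tile.astype(np.float64) / 127.5 - 1.0


def from_unit(x: np.ndarray) -> np.ndarray:
    """float in [-1, 1] -> uint8 RGB (clamped, rounded)."""
    return np.clip(np.rint((np.clip(x, -1.0, 1.0) + 1.0) * 127.5), 0, 255).astype(np.uint8)


def _lrelu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, _LEAK * x)


def _lrelu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, _LEAK)


class _PixelMLP:
    """One-hidden-layer MLP applied independently at every pixel."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator, zero_output: bool):
        self.W1 = rng.normal(0.0, 0.2, (in_dim, hidden))
        self.b1 = np.zeros(hidden)
        if zero_output:
            self.W2 = np.zeros((hidden, out_dim))
        else:
            self.W2 = rng.normal(0.0, 0.2, (hidden, out_dim))
        self.b2 = np.zeros(out_dim)

    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def set_params(self, p: dict[str, np.ndarray]) -> None:
        self.W1, self.b1 = p["W1"].copy(), p["b1"].copy()
        self.W2, self.b2 = p["W2"].copy(), p["b2"].copy()

    def forward(self, x: np.ndarray):
        pre = x @ self.W1 + self.b1
        a = _lrelu(pre)
        out = a @ self.W2 + self.b2
        return out, (x, pre, a)

    def backward(self, cache, gout: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(out); returns (param grads, dx)."""
        x, pre, a = cache
        flat = lambda t, d: t.reshape(-1, d)
        h = self.b1.shape[0]
        o = self.b2.shape[0]
        gW2 = flat(a, h).T @ flat(gout, o)
        gb2 = flat(gout, o).sum(axis=0)
        da = gout @ self.W2.T
        dpre = da * _lrelu_grad(pre)
        gW1 = flat(x, x.shape[-1]).T @ flat(dpre, h)
        gb1 = flat(dpre, h).sum(axis=0)
        dx = dpre @ self.W1.T
        return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}, dx


class Generator:
    """Residual per-pixel colour map ``x + MLP(x)``.

    With ``identity=True`` the output layer is zeroed so the generator is an
    exact pass-through, the baseline state for convergence comparisons.
    """

    def __init__(self, hidden: int = 16, rng: np.random.Generator | None = None,
                 identity: bool = False):
        rng = rng or np.random.default_rng(0)
        self.mlp = _PixelMLP(3, hidden, 3, rng, zero_output=identity)

    def forward(self, x: np.ndarray):
        res, cache = self.mlp.forward(x)
        return x + res, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, gout: np.ndarray):
        grads, dx = self.mlp.backward(cache, gout)
        return grads, gout + dx

    params = property(lambda self: self.mlp.params)


class Critic:
    """Per-pixel colour critic producing a real/virtual score map."""

    def __init__(self, hidden: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.mlp = _PixelMLP(3, hidden, 1, rng, zero_output=False)

    def forward(self, x: np.ndarray):
        s, cache = self.mlp.forward(x)
        return s[..., 0], cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, gs: np.ndarray):
        return self.mlp.backward(cache, gs[..., None])

    params = property(lambda self: self.mlp.params)


def adversarial_loss(critic: Critic, real_batch: np.ndarray, fake_batch: np.ndarray) -> dict[str, float]:
    """Least-squares GAN terms for one critic.

    Returns the discriminator loss ``mean[(D(real)-1)^2] + mean[D(fake)^2]``
    and the generator adversarial term ``mean[(D(fake)-1)^2]``.
    """
    real_batch = np.asarray(real_batch, dtype=np.float64)
    fake_batch = np.asarray(fake_batch, dtype=np.float64)
    if real_batch.shape[1:] != fake_batch.shape[1:]:
        raise ValueError("real and fake batches must share spatial shape")
    s_real = critic(real_batch)
    s_fake = critic(fake_batch)
    if not (np.isfinite(s_real).all() and np.isfinite(s_fake).all()):
        raise FloatingPointError("NaN/inf in critic activations")
    return {
        "discriminator": float(np.mean((s_real - 1.0) ** 2) + np.mean(s_fake ** 2)),
        "generator": float(np.mean((s_fake - 1.0) ** 2)),
    }


def cycle_loss(g_ab: Generator, g_ba: Generator, batch_a: np.ndarray, batch_b: np.ndarray) -> float:
    """Mean absolute reconstruction error of both round trips."""
    batch_a = np.asarray(batch_a, dtype=np.float64)
    batch_b = np.asarray(batch_b, dtype=np.float64)
    rec_a = g_ba(g_ab(batch_a))
    rec_b = g_ab(g_ba(batch_b))
    if rec_a.shape != batch_a.shape or rec_b.shape != batch_b.shape:
        raise ValueError("shape mismatch in cycle reconstruction")
    return float(np.mean(np.abs(rec_a - batch_a)) + np.mean(np.abs(rec_b - batch_b)))


@dataclass
class TrainConfig:
    """Training configuration.

    The study-scale defaults are a 200,000-iteration budget with a checkpoint
    every 5000 iterations; toy runs pass much smaller values.  Loss weights
    follow the standard unpaired-translation defaults (cycle 10, identity 5,
    least-squares adversarial); optimizer is Adam at 2e-4.
    """

    max_iterations: int = 200_000
    checkpoint_every: int = 5_000
    batch_size: int = 4
    learning_rate: float = 2e-4
    lambda_cycle: float = 10.0
    lambda_identity: float = 5.0
    crop_size: int = 256
    rng_seed: int = 0
    hidden: int = 16
    identity_init: bool = False

    def __post_init__(self) -> None:
        if self.lambda_cycle <= 0:
            raise ValueError("lambda_cycle must be > 0")
        if self.max_iterations > 0 and self.checkpoint_every > self.max_iterations:
            raise ValueError("checkpoint_every must be <= max_iterations")


@dataclass
class TranslatorState:
    """Generator/discriminator parameters at a training iteration."""

    g_ab: dict[str, np.ndarray]
    g_ba: dict[str, np.ndarray]
    d_a: dict[str, np.ndarray]
    d_b: dict[str, np.ndarray]
    iteration: int

    def __post_init__(self) -> None:
        for name, p in (("g_ab", self.g_ab), ("g_ba", self.g_ba),
                        ("d_a", self.d_a), ("d_b", self.d_b)):
            for k, v in p.items():
                if not np.isfinite(v).all():
                    raise ValueError(f"non-finite parameter {name}.{k}")
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")

    def generator(self, direction: str = "a2b") -> Generator:
        if direction not in ("a2b", "b2a"):
            raise ValueError("direction must be 'a2b' or 'b2a'")
        g = Generator(hidden=self.g_ab["b1"].shape[0])
        g.mlp.set_params(self.g_ab if direction == "a2b" else self.g_ba)
        return g


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.5, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _add_grads(acc: dict[str, np.ndarray], extra: dict[str, np.ndarray]) -> None:
    for k, v in extra.items():
        acc[k] = acc[k] + v if k in acc else v


def _l1_grad(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.sign(u - v) / u.size


def _snapshot(g_ab, g_ba, d_a, d_b, iteration) -> TranslatorState:
    cp = lambda p: {k: v.copy() for k, v in p.items()}
    return TranslatorState(cp(g_ab.params()), cp(g_ba.params()),
                           cp(d_a.params()), cp(d_b.params()), iteration)


def train(
    tiles_a: list[np.ndarray],
    tiles_b: list[np.ndarray],
    cfg: TrainConfig,
) -> tuple[list[TranslatorState], list[dict[str, float]]]:
    """Train the two-generator/two-critic system on unpaired tile sets.

    Returns the checkpoint list (iteration 0 included as the convergence
    baseline, then every ``checkpoint_every`` iterations, then the final
    state) and the per-iteration loss log.  Training stops early, returning
    the checkpoints so far, if any loss goes non-finite.
    """
    if not tiles_a or not tiles_b:
        raise ValueError("both tile sets must be nonempty")
    for t in tiles_a + tiles_b:
        if min(t.shape[0], t.shape[1]) < cfg.crop_size:
            raise ValueError("all tiles must be at least crop_size on both axes")

    rng = np.random.default_rng(cfg.rng_seed)
    g_ab = Generator(cfg.hidden, rng, identity=cfg.identity_init)
    g_ba = Generator(cfg.hidden, rng, identity=cfg.identity_init)
    d_a = Critic(cfg.hidden, rng)
    d_b = Critic(cfg.hidden, rng)
    opt_g = _Adam({**{"ab_" + k: v for k, v in g_ab.params().items()},
                   **{"ba_" + k: v for k, v in g_ba.params().items()}}, cfg.learning_rate)
    opt_da = _Adam(d_a.params(), cfg.learning_rate)
    opt_db = _Adam(d_b.params(), cfg.learning_rate)

    from .tiling import random_crop

    def sample_batch(tiles: list[np.ndarray]) -> np.ndarray:
        idx = rng.integers(0, len(tiles), size=cfg.batch_size)
        crops = [random_crop(tiles[i], cfg.crop_size, rng) for i in idx]
        return to_unit(np.stack(crops))

    checkpoints = [_snapshot(g_ab, g_ba, d_a, d_b, 0)]
    log: list[dict[str, float]] = []

    for it in range(1, cfg.max_iterations + 1):
        a = sample_batch(tiles_a)
        b = sample_batch(tiles_b)

        fake_b, cache_fb = g_ab.forward(a)
        fake_a, cache_fa = g_ba.forward(b)

        # --- critic updates (fakes detached) ---
        critic_passes = []
        d_losses = {}
        for critic, opt, real, fake, tag in ((d_a, opt_da, a, fake_a, "d_a"),
                                             (d_b, opt_db, b, fake_b, "d_b")):
            s_real, c_real = critic.forward(real)
            s_fake, c_fake = critic.forward(fake)
            d_losses[tag] = float(np.mean((s_real - 1) ** 2) + np.mean(s_fake ** 2))
            critic_passes.append((critic, opt, s_real, c_real, s_fake, c_fake))
        if not all(np.isfinite(v) for v in d_losses.values()):
            logger.warning("non-finite critic loss at iteration %d; stopping early", it)
            break
        for critic, opt, s_real, c_real, s_fake, c_fake in critic_passes:
            grads, _ = critic.backward(c_real, 2 * (s_real - 1) / s_real.size)
            g2, _ = critic.backward(c_fake, 2 * s_fake / s_fake.size)
            _add_grads(grads, g2)
            opt.step(critic.params(), grads)

        # --- generator update ---
        rec_a, cache_ra = g_ba.forward(fake_b)
        rec_b, cache_rb = g_ab.forward(fake_a)
        id_b, cache_ib = g_ab.forward(b)
        id_a, cache_ia = g_ba.forward(a)
        s_fb, cache_sfb = d_b.forward(fake_b)
        s_fa, cache_sfa = d_a.forward(fake_a)

        loss_cyc = float(np.mean(np.abs(rec_a - a)) + np.mean(np.abs(rec_b - b)))
        loss_id = float(np.mean(np.abs(id_b - b)) + np.mean(np.abs(id_a - a)))
        loss_adv = float(np.mean((s_fb - 1) ** 2) + np.mean((s_fa - 1) ** 2))
        total = loss_adv + cfg.lambda_cycle * loss_cyc + cfg.lambda_identity * loss_id

        if not np.isfinite(total):
            logger.warning("non-finite generator loss at iteration %d; stopping early", it)
            break

        gab_grads: dict[str, np.ndarray] = {}
        gba_grads: dict[str, np.ndarray] = {}

        # cycle A: rec_a = g_ba(g_ab(a))
        gr, d_fake_b = g_ba.backward(cache_ra, cfg.lambda_cycle * _l1_grad(rec_a, a))
        _add_grads(gba_grads, gr)
        # cycle B: rec_b = g_ab(g_ba(b))
        gr, d_fake_a = g_ab.backward(cache_rb, cfg.lambda_cycle * _l1_grad(rec_b, b))
        _add_grads(gab_grads, gr)
        # adversarial terms flow into the fakes through the (frozen) critics
        _, dxb = d_b.backward(cache_sfb, 2 * (s_fb - 1) / s_fb.size)
        _, dxa = d_a.backward(cache_sfa, 2 * (s_fa - 1) / s_fa.size)
        gr, _ = g_ab.backward(cache_fb, d_fake_b + dxb)
        _add_grads(gab_grads, gr)
        gr, _ = g_ba.backward(cache_fa, d_fake_a + dxa)
        _add_grads(gba_grads, gr)
        # identity terms
        gr, _ = g_ab.backward(cache_ib, cfg.lambda_identity * _l1_grad(id_b, b))
        _add_grads(gab_grads, gr)
        gr, _ = g_ba.backward(cache_ia, cfg.lambda_identity * _l1_grad(id_a, a))
        _add_grads(gba_grads, gr)

        joint = {**{"ab_" + k: v for k, v in g_ab.params().items()},
                 **{"ba_" + k: v for k, v in g_ba.params().items()}}
        joint_grads = {**{"ab_" + k: v for k, v in gab_grads.items()},
                       **{"ba_" + k: v for k, v in gba_grads.items()}}
        opt_g.step(joint, joint_grads)
        for k in g_ab.params():
            g_ab.params()[k][...] = joint["ab_" + k]
            g_ba.params()[k][...] = joint["ba_" + k]

        log.append({"iteration": it, "loss_total": total, "loss_cycle": loss_cyc,
                    "loss_identity": loss_id, "loss_adversarial": loss_adv,
                    "loss_d_a": d_losses["d_a"], "loss_d_b": d_losses["d_b"]})

        if it % cfg.checkpoint_every == 0:
            checkpoints.append(_snapshot(g_ab, g_ba, d_a, d_b, it))

    if not checkpoints or checkpoints[-1].iteration != min(cfg.max_iterations, len(log)):
        checkpoints.append(_snapshot(g_ab, g_ba, d_a, d_b, len(log)))
    return checkpoints, log


def translate_tile(state: TranslatorState, tile: np.ndarray, direction: str = "a2b") -> np.ndarray:
    """Translate one 8-bit RGB tile; output has the same spatial dims."""
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("tile must be HxWx3 RGB")
    g = state.generator(direction)
    return from_unit(g(to_unit(tile)))


def save_checkpoint(state: TranslatorState, path: str | Path,
                    losses: dict | None = None, config: TrainConfig | None = None) -> None:
    """Single-file parameter archive plus a JSON sidecar."""
    path = Path(path)
    arrays = {}
    for group, params in (("g_ab", state.g_ab), ("g_ba", state.g_ba),
                          ("d_a", state.d_a), ("d_b", state.d_b)):
        for k, v in params.items():
            arrays[f"{group}.{k}"] = v
    np.savez(path, iteration=state.iteration, **arrays)
    sidecar = {"iteration": state.iteration}
    if losses:
        sidecar["losses"] = losses
    if config:
        sidecar["config"] = {k: getattr(config, k) for k in config.__dataclass_fields__}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_checkpoint(path: str | Path) -> TranslatorState:
    with np.load(Path(path)) as z:
        groups: dict[str, dict[str, np.ndarray]] = {"g_ab": {}, "g_ba": {}, "d_a": {}, "d_b": {}}
        for key in z.files:
            if key == "iteration":
                continue
            group, name = key.split(".", 1)
            groups[group][name] = z[key]
        return TranslatorState(groups["g_ab"], groups["g_ba"], groups["d_a"],
                               groups["d_b"], int(z["iteration"]))
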
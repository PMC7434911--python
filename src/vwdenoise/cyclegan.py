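"""Unsupervised denoiser: CycleGAN between noisy (A) and clean (B) domains.

Two U-Net generators (G_AB, G_BA) and two convolutional discriminators
(D_A, D_B) are trained jointly on unpaired domains with least-squares
adversarial losses and an L1 cycle-consistency penalty:

    L = L_GAN(G_AB, D_B) + L_GAN(G_BA, D_A) + lambda * L_cyclic(G_AB, G_BA)

The discriminator stacks five 4x4 stride-2 convolutions (instance
normalisation and leaky ReLU after each except no normalisation on the
first), a 1x1 "fully connected" convolution, and a global average pool down
to one scalar per image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .phantom import GrayImage, UnpairedDataset
from .selfsup import UNet, UNetConfig, _normalise


@dataclass
class CycleGANConfig:
    """Generator/discriminator architecture and optimisation settings.

    Desk-scale defaults (small nets, 64x64 inputs, few epochs) keep a CPU run
    in minutes; the full-scale study values are ``epochs=200,
    learning_rate=0.002`` on 640x640 inputs.
    """

    generator: UNetConfig = field(default_factory=lambda: UNetConfig(depth=3, base_channels=8))
    disc_base_channels: int = 8
    lambda_cyclic: float = 10.0
    epochs: int = 8
    learning_rate: float = 0.002
    input_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.lambda_cyclic < 0:
            raise ValueError("lambda_cyclic must be >= 0")
        if self.lambda_cyclic == 0:
            warnings.warn("lambda_cyclic = 0: pure GAN with no cycle constraint",
                          RuntimeWarning, stacklevel=2)
        if self.epochs < 1 or self.learning_rate <= 0 or self.input_size < 16:
            raise ValueError("epochs, learning_rate and input_size must be positive")


def build_discriminator(base_channels: int, seed: int = 0) -> nn.Sequential:
    """Five 4x4 stride-2 convolutions + 1x1 FC + global average pool -> scalar."""
    rng = np.random.default_rng(seed)
    c = base_channels
    chans = [c, 2 * c, 4 * c, 8 * c, 8 * c]
    layers = [nn.Conv2d(1, chans[0], 4, stride=2, pad=1, rng=rng), nn.LeakyReLU(0.2)]
    for i in range(1, 5):
        layers += [nn.Conv2d(chans[i - 1], chans[i], 4, stride=2, pad=1, rng=rng),
                   nn.InstanceNorm2d(chans[i]), nn.LeakyReLU(0.2)]
    layers += [nn.Conv2d(chans[4], 1, 1, pad=0, rng=rng), nn.GlobalAvgPool()]
    return nn.Sequential(*layers)


@dataclass
class CycleGANModel:
    """Both generators, both discriminators and the training loss log."""

    G_AB: UNet
    G_BA: UNet
    D_A: nn.Sequential
    D_B: nn.Sequential
    config: CycleGANConfig
    loss_log: list = field(default_factory=list)  # per-epoch dicts
    trained: bool = False

    def _nets(self):
        return {"G_AB": self.G_AB, "G_BA": self.G_BA, "D_A": self.D_A, "D_B": self.D_B}

    def save(self, path) -> None:
        state = {}
        for name, net in self._nets().items():
            for k, v in nn.state_dict(net).items():
                state[f"{name}/{k}"] = v
        meta = {
            "generator": asdict(self.config.generator),
            "config": {k: v for k, v in asdict(self.config).items() if k != "generator"},
            "loss_log": self.loss_log,
            "trained": self.trained,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "CycleGANModel":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            config = CycleGANConfig(generator=UNetConfig(**meta["generator"]), **meta["config"])
        model = build_cyclegan(config)
        model.loss_log = [dict(e) for e in meta["loss_log"]]
        model.trained = meta["trained"]
        for name, net in model._nets().items():
            sub = {k.split("/", 1)[1]: v for k, v in state.items() if k.startswith(name + "/")}
            nn.load_state_dict(net, sub)
        return model


def build_cyclegan(config: CycleGANConfig | None = None) -> CycleGANModel:
    config = config or CycleGANConfig()
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2 ** 31)
    return CycleGANModel(
        G_AB=UNet(config.generator, seed=int(seeds[0])),
        G_BA=UNet(config.generator, seed=int(seeds[1])),
        D_A=build_discriminator(config.disc_base_channels, seed=int(seeds[2])),
        D_B=build_discriminator(config.disc_base_channels, seed=int(seeds[3])),
        config=config,
    )


def lsgan_losses(disc_real, disc_fake):
    """Least-squares GAN terms from discriminator outputs.

    Returns ``(generator_term, discriminator_term)`` where the generator term
    is ``E[(1 - D(G(x)))^2]`` and the discriminator term
    ``E[(D(real) - 1)^2] + E[D(fake)^2]``.
    """
    dr = np.asarray(disc_real, dtype=np.float64)
    df = np.asarray(disc_fake, dtype=np.float64)
    if not (np.all(np.isfinite(dr)) and np.all(np.isfinite(df))):
        raise ValueError("discriminator outputs must be finite")
    gen = float(np.mean((1.0 - df) ** 2))
    disc = float(np.mean((dr - 1.0) ** 2) + np.mean(df ** 2))
    return gen, disc


def _apply(gen, x):
    out = gen(x)
    return np.asarray(out, dtype=np.float64)


def cyclic_loss(x_A, x_B, G_AB, G_BA) -> float:
    """L1 cycle-consistency: ``|G_BA(G_AB(x_A)) - x_A| + |G_AB(G_BA(x_B)) - x_B|``
    (mean absolute error per direction). Generators are callables on arrays."""
    a = np.asarray(x_A.pixels if isinstance(x_A, GrayImage) else x_A, dtype=np.float64)
    b = np.asarray(x_B.pixels if isinstance(x_B, GrayImage) else x_B, dtype=np.float64)
    rec_a = _apply(G_BA, _apply(G_AB, a))
    rec_b = _apply(G_AB, _apply(G_BA, b))
    if rec_a.shape != a.shape or rec_b.shape != b.shape:
        raise ValueError("generators must preserve shape")
    return float(np.mean(np.abs(rec_a - a)) + np.mean(np.abs(rec_b - b)))


def _prep(images, size):
    out = []
    for img in images:
        arr = np.asarray(img.pixels if isinstance(img, GrayImage) else img, dtype=nn.DTYPE)
        if arr.shape[0] < size or arr.shape[1] < size:
            raise ValueError("images smaller than the configured input size")
        arr = arr[:size, :size]
        z, _, _ = _normalise(arr)
        out.append(z.astype(nn.DTYPE))
    return out


def train_cyclegan(data: UnpairedDataset, config: CycleGANConfig | None = None) -> CycleGANModel:
    """Alternating least-squares GAN / cycle updates, one step per image pair.

    Each step performs one generator update (both directions, adversarial +
    weighted cyclic terms) followed by one update of each discriminator on a
    freshly generated fake.  Seeded and deterministic for a fixed thread
    count; raises on non-finite losses.
    """
    config = config or CycleGANConfig()
    model = build_cyclegan(config)
    rng = np.random.default_rng(config.seed)
    lam = config.lambda_cyclic
    A = _prep(data.domain_A, config.input_size)
    B = _prep(data.domain_B, config.input_size)
    G_AB, G_BA, D_A, D_B = model.G_AB, model.G_BA, model.D_A, model.D_B
    opt_G = nn.Adam({**{f"ab.{k}": p for k, p in G_AB.params().items()},
                     **{f"ba.{k}": p for k, p in G_BA.params().items()}},
                    lr=config.learning_rate, betas=(0.5, 0.999))
    opt_DA = nn.Adam(D_A.params(), lr=config.learning_rate, betas=(0.5, 0.999))
    opt_DB = nn.Adam(D_B.params(), lr=config.learning_rate, betas=(0.5, 0.999))

    def gen_half_step(x_src, G_fwd, G_inv, D_tgt):
        """One direction of the generator objective; accumulates G grads.

        Returns (adversarial term, cyclic term, fake image)."""
        x = x_src[None, None]
        fake = G_fwd.forward(x, train=True)
        d_out = D_tgt.forward(fake, train=True)  # (1, 1)
        adv = float(np.mean((1.0 - d_out) ** 2))
        d_grad = (-2.0 * (1.0 - d_out) / d_out.size).astype(nn.DTYPE)
        g_fake_adv = D_tgt.backward(d_grad)
        rec = G_inv.forward(fake, train=True)
        cyc, cyc_grad = nn.l1_loss(rec, x)
        g_fake_cyc = G_inv.backward((lam * cyc_grad).astype(nn.DTYPE))
        G_fwd.backward(g_fake_adv + g_fake_cyc)
        return adv, cyc, fake[0, 0].copy()

    def disc_step(D, opt, real, fake):
        opt.zero_grad()
        d_real = D.forward(real[None, None], train=True)
        D.backward((2.0 * (d_real - 1.0) / d_real.size).astype(nn.DTYPE))
        d_fake = D.forward(fake[None, None], train=True)
        D.backward((2.0 * d_fake / d_fake.size).astype(nn.DTYPE))
        opt.step()
        return lsgan_losses(d_real, d_fake)[1]

    for epoch in range(config.epochs):
        order_a = rng.permutation(len(A))
        order_b = rng.permutation(len(B))
        n_steps = max(len(A), len(B))
        acc = {"gan_ab": 0.0, "gan_ba": 0.0, "cyclic": 0.0, "disc_a": 0.0, "disc_b": 0.0}
        for step in range(n_steps):
            x_a = A[order_a[step % len(A)]]
            x_b = B[order_b[step % len(B)]]
            opt_G.zero_grad()
            adv_ab, cyc_a, fake_b = gen_half_step(x_a, G_AB, G_BA, D_B)
            adv_ba, cyc_b, fake_a = gen_half_step(x_b, G_BA, G_AB, D_A)
            opt_G.step()
            acc["gan_ab"] += adv_ab
            acc["gan_ba"] += adv_ba
            acc["cyclic"] += cyc_a + cyc_b
            acc["disc_b"] += disc_step(D_B, opt_DB, x_b, fake_b)
            acc["disc_a"] += disc_step(D_A, opt_DA, x_a, fake_a)
        entry = {k: v / n_steps for k, v in acc.items()}
        entry["epoch"] = epoch
        entry["total"] = entry["gan_ab"] + entry["gan_ba"] + lam * entry["cyclic"]
        if not all(np.isfinite(v) for v in entry.values()):
            raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
        model.loss_log.append(entry)
    model.trained = True
    return model


def translate(model: CycleGANModel, image: GrayImage, direction: str = "ab") -> GrayImage:
    """Apply a trained generator (``'ab'``: noisy->clean, ``'ba'``: clean->noisy)."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    if direction not in ("ab", "ba"):
        raise ValueError("direction must be 'ab' or 'ba'")
    gen = model.G_AB if direction == "ab" else model.G_BA
    side = 2 ** model.config.generator.depth
    arr = np.asarray(image.pixels, dtype=nn.DTYPE)
    z, mu, sd = _normalise(arr)
    h, w = z.shape
    ph, pw = (-h) % side, (-w) % side
    if ph or pw:
        z = np.pad(z, ((0, ph), (0, pw)), mode="reflect")
    out = gen.forward(z[None, None].astype(nn.DTYPE), train=False)[0, 0][:h, :w]
    return GrayImage(pixels=(out * sd + mu).astype(np.float64), pixel_spacing=image.pixel_spacing)
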
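"""Self-supervised denoiser: a single-channel U-Net trained with MSE.

The training pairs are pixel-aligned (artificially corrupted, clean) images;
the trained network is then applied to independently corrupted images.  The
noisy-target variant (``noisy_targets=True`` in :func:`train_denoiser`) trains
against an independently re-corrupted copy of the clean image instead of the
clean image itself; because the corruption is zero-mean, the MSE minimiser is
unchanged in expectation and the trained network should denoise almost as well
as the clean-target one.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .phantom import GrayImage, PairedDataset


@dataclass
class UNetConfig:
    """Architecture of the single-channel encoder/decoder network.

    ``depth`` encoder levels of two 3x3 conv + batch-norm + ReLU blocks,
    2x2 max-pool down-sampling, 2x2 transposed-convolution up-sampling and
    skip connections at matching resolutions.  Channel count doubles per
    level starting from ``base_channels``.
    """

    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.in_channels != 1 or self.out_channels != 1:
            raise ValueError("the denoiser is single-channel in and out")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults are desk scale (small patches, few epochs) so the pipeline runs
    on one CPU; the full-scale values reported for the clinical study are
    ``epochs=200, learning_rate=0.002, patch_size=256``.
    """

    epochs: int = 20
    learning_rate: float = 0.002
    patch_size: int = 64
    batch_size: int = 8
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self):
        if min(self.epochs, self.patch_size, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, patch_size, batch_size, learning_rate must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


class _ConvBlock(nn.Layer):
    """(Conv3x3 -> BatchNorm -> ReLU) x2; batch norm sits before activation."""

    def __init__(self, c_in, c_out, rng):
        self.seq = nn.Sequential(
            nn.Conv2d(c_in, c_out, 3, bias=False, rng=rng),
            nn.BatchNorm2d(c_out),
            nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, bias=False, rng=rng),
            nn.BatchNorm2d(c_out),
            nn.ReLU(),
        )

    def forward(self, x, train=True):
        return self.seq.forward(x, train=train)

    def backward(self, dy):
        return self.seq.backward(dy)

    def params(self):
        return {f"seq.{k}": p for k, p in self.seq.params().items()}

    def buffers(self):
        return {f"seq.{k}": b for k, b in self.seq.buffers().items()}

    def load_buffers(self, state):
        self.seq.load_buffers({k.split(".", 1)[1]: v for k, v in state.items()})


class UNet(nn.Layer):
    """U-Net with skip connections, explicit forward/backward."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        d = config.depth
        self.enc = []
        ch_in = config.in_channels
        for i in range(d):
            self.enc.append(_ConvBlock(ch_in, c * 2 ** i, rng))
            ch_in = c * 2 ** i
        self.pools = [nn.MaxPool2x2() for _ in range(d)]
        self.bottleneck = _ConvBlock(ch_in, c * 2 ** d, rng)
        self.ups = []
        self.dec = []
        ch = c * 2 ** d
        for i in reversed(range(d)):
            self.ups.append(nn.ConvTranspose2x2(ch, c * 2 ** i, rng=rng))
            self.dec.append(_ConvBlock(2 * c * 2 ** i, c * 2 ** i, rng))
            ch = c * 2 ** i
        self.head = nn.Conv2d(ch, config.out_channels, 1, pad=0, rng=rng)
        self._skip_channels = [c * 2 ** i for i in range(d)]

    def _modules(self):
        mods = {}
        for i, m in enumerate(self.enc):
            mods[f"enc{i}"] = m
        mods["bottleneck"] = self.bottleneck
        for i, m in enumerate(self.ups):
            mods[f"up{i}"] = m
        for i, m in enumerate(self.dec):
            mods[f"dec{i}"] = m
        mods["head"] = self.head
        return mods

    def params(self):
        return {f"{name}.{k}": p for name, m in self._modules().items() for k, p in m.params().items()}

    def buffers(self):
        return {f"{name}.{k}": b for name, m in self._modules().items() for k, b in m.buffers().items()}

    def load_buffers(self, state):
        for name, m in self._modules().items():
            sub = {k.split(".", 1)[1]: v for k, v in state.items() if k.startswith(name + ".")}
            if sub:
                m.load_buffers(sub)

    def batch_norms(self):
        out = []
        for m in self._modules().values():
            seq = getattr(m, "seq", None)
            if seq is not None:
                out.extend(l for l in seq.layers if isinstance(l, nn.BatchNorm2d))
        return out

    def forward(self, x, train=True):
        d = self.config.depth
        if x.shape[2] % 2 ** d or x.shape[3] % 2 ** d:
            raise ValueError(f"input sides must be divisible by {2 ** d}")
        skips = []
        for i in range(d):
            x = self.enc[i].forward(x, train=train)
            skips.append(x)
            x = self.pools[i].forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        for j, i in enumerate(reversed(range(d))):
            x = self.ups[j].forward(x, train=train)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[j].forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dy):
        d = self.config.depth
        dy = self.head.backward(dy)
        dskips = [None] * d
        for j in reversed(range(d)):
            i = d - 1 - j
            dy = self.dec[j].backward(dy)
            csk = self._skip_channels[i]
            dskips[i] = dy[:, :csk]
            dy = self.ups[j].backward(dy[:, csk:])
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(d)):
            dy = self.pools[i].backward(dy)
            dy = self.enc[i].backward(dy + dskips[i])
        return dy


@dataclass
class DenoiserModel:
    """A U-Net denoiser plus its training provenance."""

    net: UNet
    unet_config: UNetConfig
    train_config: TrainConfig | None = None
    loss_log: list = field(default_factory=list)  # (epoch, train_mse, val_mse)
    trained: bool = False

    def save(self, path) -> None:
        state = nn.state_dict(self.net)
        meta = {
            "unet_config": asdict(self.unet_config),
            "train_config": asdict(self.train_config) if self.train_config else None,
            "loss_log": self.loss_log,
            "trained": self.trained,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        with np.load(path if isinstance(path, _io.IOBase) else str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = UNetConfig(**meta["unet_config"])
        net = UNet(cfg, seed=0)
        for k, p in net.params().items():
            p.value[...] = state[f"p:{k}"]
        net.load_buffers({k: state[f"b:{k}"] for k in net.buffers()})
        tc = TrainConfig(**meta["train_config"]) if meta["train_config"] else None
        return cls(net=net, unet_config=cfg, train_config=tc,
                   loss_log=[tuple(e) for e in meta["loss_log"]], trained=meta["trained"])


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> DenoiserModel:
    """An untrained denoiser with seeded parameter initialisation."""
    config = config or UNetConfig()
    return DenoiserModel(net=UNet(config, seed=seed), unet_config=config)


def _normalise(arr: np.ndarray):
    mu, sd = float(arr.mean()), float(arr.std())
    if sd == 0:
        sd = 1.0
    return (arr - mu) / sd, mu, sd


def _random_patch(rng, a: np.ndarray, b: np.ndarray, size: int):
    h, w = a.shape
    r = rng.integers(0, h - size + 1) if h > size else 0
    c = rng.integers(0, w - size + 1) if w > size else 0
    return a[r : r + size, c : c + size], b[r : r + size, c : c + size]


def train_denoiser(pairs: PairedDataset, unet: UNetConfig | None = None,
                   train: TrainConfig | None = None, *, noisy_targets: bool = False,
                   noise_spec=None) -> DenoiserModel:
    """Train the U-Net on aligned (corrupted, clean) pairs with MSE loss.

    With ``noisy_targets=True`` each target is replaced by an independently
    re-corrupted copy of the clean image (requires ``noise_spec``); the clean
    images themselves are never shown to the network in that mode.
    """
    unet = unet or UNetConfig()
    train = train or TrainConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    side = 2 ** unet.depth
    patch = train.patch_size
    if patch % side:
        raise ValueError(f"patch_size must be divisible by {side}")
    if noisy_targets and noise_spec is None:
        raise ValueError("noisy_targets=True requires a noise_spec")

    rng = np.random.default_rng(train.seed)
    model = build_unet(unet, seed=train.seed)
    net = model.net
    opt = nn.Adam(net.params(), lr=train.learning_rate)

    data = []
    for idx, (noisy, clean) in enumerate(pairs):
        target = clean.pixels
        if noisy_targets:
            from .corruption import add_noise
            target = add_noise(clean, noise_spec, seed=int(rng.integers(2 ** 31))).pixels
        xn, _, _ = _normalise(np.asarray(noisy.pixels, dtype=nn.DTYPE))
        yn, _, _ = _normalise(np.asarray(target, dtype=nn.DTYPE))
        data.append((xn.astype(nn.DTYPE), yn.astype(nn.DTYPE)))

    n_val = int(round(train.validation_fraction * len(data)))
    n_val = min(n_val, len(data) - 2)
    val, trn = data[:n_val], data[n_val:]

    def eval_mse(split):
        if not split:
            return float("nan")
        tot = 0.0
        for x, y in split:
            xp, yp = x[:patch, :patch], y[:patch, :patch]
            out = net.forward(xp[None, None], train=False)
            tot += float(np.mean((out[0, 0] - yp) ** 2))
        return tot / len(split)

    model.loss_log.append((-1, eval_mse(trn), eval_mse(val)))
    for epoch in range(train.epochs):
        order = rng.permutation(len(trn))
        tot, nb = 0.0, 0
        for start in range(0, len(order), train.batch_size):
            chunk = order[start : start + train.batch_size]
            xs, ys = [], []
            for i in chunk:
                xp, yp = _random_patch(rng, trn[i][0], trn[i][1], patch)
                xs.append(xp)
                ys.append(yp)
            xb = np.stack(xs)[:, None]
            yb = np.stack(ys)[:, None]
            opt.zero_grad()
            out = net.forward(xb, train=True)
            loss, grad = nn.mse_loss(out, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            net.backward(grad.astype(nn.DTYPE))
            opt.step()
            tot += loss
            nb += 1
        model.loss_log.append((epoch, tot / max(nb, 1), eval_mse(val)))

    # freeze batch-norm inference statistics as the aggregate batch statistics
    # over the training set (a single calibration sweep, deterministic crops)
    bns = net.batch_norms()
    for i, start in enumerate(range(0, len(trn), train.batch_size)):
        xb = np.stack([x[:patch, :patch] for x, _ in trn[start : start + train.batch_size]])[:, None]
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        net.forward(xb.astype(nn.DTYPE), train=True)
    for bn in bns:
        bn.momentum = 0.1
    model.train_config = train
    model.trained = True
    return model


def denoise(model: DenoiserModel, image: GrayImage) -> GrayImage:
    """Apply a trained denoiser; arbitrary sizes handled by reflect pad-and-crop."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    side = 2 ** model.unet_config.depth
    arr = np.asarray(image.pixels, dtype=nn.DTYPE)
    xn, mu, sd = _normalise(arr)
    h, w = xn.shape
    ph = (-h) % side
    pw = (-w) % side
    if ph or pw:
        xn = np.pad(xn, ((0, ph), (0, pw)), mode="reflect")
    out = model.net.forward(xn[None, None].astype(nn.DTYPE), train=False)[0, 0]
    out = out[:h, :w] * sd + mu
    return GrayImage(pixels=out.astype(np.float64), pixel_spacing=image.pixel_spacing)
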
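"""Learned low-frequency bandwidth extension of shot gathers.

Band-limited probes record nothing below their low-frequency cutoff, yet
frequency-stepped FWI needs exactly that band to avoid cycle skipping.
This module trains networks to predict broadband gather windows from
band-limited (plus noise) windows of the *same* acquisition, using
simulated phantom data where both versions exist:

* a 2D U-Net over time x element windows, exploiting wavefront
  continuity across neighbouring elements;
* a five-stage 1D CNN (PReLU + batch norm) over individual traces, the
  trace-by-trace baseline the U-Net is compared against.

Windows are augmented by random time shifts and element-order flips.
Inference tiles full-length traces with overlapping cosine-blended
windows. Inputs are normalized per window by their max-abs; the target
shares the input's scale so predictions return to physical amplitude by
multiplying back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .signals import Wavelet
from .wavesim import USCTDataset


def augmentation_count(
    n_datasets: int = 4, n_gathers: int = 3072, n_shifts: int = 288,
    n_flips: int = 2,
) -> int:
    """Distinct augmented windows available to sample: every (dataset,
    gather, shift, flip) combination. The printed full-scale training
    configuration (4 datasets x 3072 gathers x 288 shifts x 2 flips)
    yields 7,077,888."""
    return n_datasets * n_gathers * n_shifts * n_flips


@dataclass
class SamplePair:
    """One training example: band-limited input window and its broadband
    target, cut from the same (source, probe) gather at the same offset."""

    input_window: np.ndarray   # (window_t, window_x)
    target_window: np.ndarray
    offset: int
    flip: bool
    provenance: tuple = ()

    def __post_init__(self):
        if self.input_window.shape != self.target_window.shape:
            raise ValueError("input/target window shape mismatch")


def make_pairs(
    bandlimited: USCTDataset,
    broadband: USCTDataset,
    n_samples: int,
    seed: int = 0,
    window_t: int = 256,
    window_x: int = 96,
    shift: int = 144,
) -> list[SamplePair]:
    """Uniformly sample augmented (gather, shift, flip) window pairs.

    Shifts are drawn from the half-open range [-shift, shift), giving
    2*shift distinct values; the flip reverses element order in input and
    target alike. Deterministic per seed.
    """
    keys = sorted(set(bandlimited.gathers) & set(broadband.gathers))
    if not keys:
        raise ValueError("datasets share no gathers")
    if abs(bandlimited.dt - broadband.dt) > 1e-15:
        raise ValueError("dt mismatch between datasets")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_samples):
        key = keys[rng.integers(len(keys))]
        g_in, g_tg = bandlimited.gathers[key], broadband.gathers[key]
        n_t, n_x = g_in.traces.shape
        if n_x < window_x:
            raise ValueError(f"gather has {n_x} traces, window needs {window_x}")
        need = window_t + 2 * shift
        if n_t < need:
            raise ValueError(
                f"trace length {n_t} too short: window {window_t} with "
                f"+/-{shift} shifts needs at least {need} samples"
            )
        s = int(rng.integers(-shift, shift))  # half-open [-shift, shift)
        flip = bool(rng.integers(2))
        base = (n_t - window_t) // 2 + s
        x0 = 0 if n_x == window_x else int(rng.integers(n_x - window_x + 1))
        win_in = np.array(g_in.traces[base:base + window_t, x0:x0 + window_x],
                          dtype=np.float64)
        win_tg = np.array(g_tg.traces[base:base + window_t, x0:x0 + window_x],
                          dtype=np.float64)
        if flip:
            win_in = win_in[:, ::-1].copy()
            win_tg = win_tg[:, ::-1].copy()
        pairs.append(SamplePair(win_in, win_tg, s, flip,
                                provenance=(bandlimited.label, key)))
    return pairs


# ---------------------------------------------------------------------
# architectures


@dataclass
class UNetConfig:
    depth: int = 3
    base_channels: int = 8
    kernel: int = 3
    seed: int = 0


@dataclass
class CNN1dConfig:
    channels: tuple[int, ...] = (16, 32, 32, 16)  # four hidden stages
    kernel: int = 15
    seed: int = 0


class _Block(nn.Layer):
    """conv-ReLU-conv-ReLU."""

    def __init__(self, c_in, c_out, k, rng):
        self.seq = nn.Sequential(
            nn.Conv2d(c_in, c_out, k, rng), nn.ReLU(),
            nn.Conv2d(c_out, c_out, k, rng), nn.ReLU(),
        )

    def params(self):
        return self.seq.params()

    def forward(self, x, train=True):
        return self.seq.forward(x, train=train)

    def backward(self, dy):
        return self.seq.backward(dy)


class UNet2d(nn.Layer):
    """Encoder-decoder with concatenated skip connections.

    Each encoder level doubles the channel count and halves both spatial
    axes; the decoder mirrors it, concatenating the matching encoder
    feature map before each decoding block. Output is a single channel of
    the input's spatial shape.
    """

    def __init__(self, cfg: UNetConfig):
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth + 1)]
        self.cfg = cfg
        self.enc = [_Block(1 if i == 0 else ch[i - 1], ch[i], cfg.kernel, rng)
                    for i in range(cfg.depth)]
        self.pools = [nn.MaxPool2d() for _ in range(cfg.depth)]
        self.bottleneck = _Block(ch[cfg.depth - 1], ch[cfg.depth], cfg.kernel, rng)
        self.ups = [nn.Upsample2d() for _ in range(cfg.depth)]
        self.dec = [
            _Block(ch[i + 1] + ch[i], ch[i], cfg.kernel, rng)
            for i in reversed(range(cfg.depth))
        ]
        self.head = nn.Conv2d(ch[0], 1, 1, rng)

    def params(self):
        ps = []
        for b in self.enc + [self.bottleneck] + self.dec + [self.head]:
            ps.extend(b.params())
        return ps

    def check_shape(self, h, w):
        f = 2**self.cfg.depth
        if h % f or w % f:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={f}; "
                f"reduce depth or pad the window"
            )

    def forward(self, x, train=True):
        self.check_shape(*x.shape[2:])
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_channels.append((skip.shape[1], x.shape[1]))
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dy):
        dy = self.head.backward(dy)
        # decoder stage s consumed encoder level (depth-1-s); walking the
        # stages in reverse therefore yields skip gradients for levels
        # 0, 1, ..., depth-1 in that order
        dskips = []
        for s in reversed(range(len(self.dec))):
            dy = self.dec[s].backward(dy)
            c_skip, _ = self._skip_channels[s]
            dskips.append(dy[:, :c_skip])
            dy = self.ups[s].backward(dy[:, c_skip:])
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(len(self.enc))):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)
        return dy

    def encoder_feature_shapes(self, h, w):
        """(encoder output shape, decoder partner shape) per level — the
        skip-connection shape audit."""
        self.check_shape(h, w)
        cfg = self.cfg
        shapes = []
        hh, ww = h, w
        for i in range(cfg.depth):
            enc_shape = (cfg.base_channels * 2**i, hh, ww)
            shapes.append((enc_shape, enc_shape))
            hh, ww = hh // 2, ww // 2
        return shapes


class CNN1d(nn.Layer):
    """Five convolutional stages over single traces: four hidden stages
    with PReLU and batch normalization, plus a linear projection
    convolution back to one channel."""

    def __init__(self, cfg: CNN1dConfig):
        rng = np.random.default_rng(cfg.seed)
        layers = []
        c_prev = 1
        for c in cfg.channels:
            layers += [nn.Conv1d(c_prev, c, cfg.kernel, rng),
                       nn.BatchNorm(c), nn.PReLU(c)]
            c_prev = c
        layers.append(nn.Conv1d(c_prev, 1, cfg.kernel, rng))
        self.seq = nn.Sequential(*layers)

    def params(self):
        return self.seq.params()

    def forward(self, x, train=True):
        return self.seq.forward(x, train=train)

    def backward(self, dy):
        return self.seq.backward(dy)

    def conv_stages(self) -> int:
        return sum(1 for l in self.seq.layers if isinstance(l, nn.Conv1d))


@dataclass
class BandextModel:
    """A trained (or initialized) bandwidth-extension network."""

    kind: str  # "unet2d" | "cnn1d"
    net: nn.Layer
    config: object
    train_seed: int | None = None
    history: dict = field(default_factory=dict)

    def predict_window(self, window: np.ndarray) -> np.ndarray:
        """Apply to one (window_t, window_x) block at physical scale."""
        scale = np.abs(window).max()
        if scale == 0:
            return np.zeros_like(window)
        w = np.asarray(window / scale, dtype=nn.DEFAULT_DTYPE)
        if self.kind == "unet2d":
            out = self.net.forward(w[None, None], train=False)[0, 0]
        else:
            x = w.T[:, None, :]  # (n_traces, 1, window_t)
            out = self.net.forward(x, train=False)[:, 0, :].T
        return out * scale

    def n_parameters(self) -> int:
        return nn.n_parameters(self.net)

    # -- persistence: npz weights + json sidecar ----------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        meta = {"kind": self.kind, "config": cfg, "train_seed": self.train_seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "BandextModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = meta["config"]
        if meta["kind"] == "unet2d":
            cfg = UNetConfig(**cfg_d)
            model = build_unet(cfg)
        else:
            cfg_d["channels"] = tuple(cfg_d["channels"])
            cfg = CNN1dConfig(**cfg_d)
            model = build_cnn1d(cfg)
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"p{i}"]
        model.train_seed = meta.get("train_seed")
        return model


def build_unet(config: UNetConfig | None = None) -> BandextModel:
    config = config or UNetConfig()
    return BandextModel("unet2d", UNet2d(config), config)


def build_cnn1d(config: CNN1dConfig | None = None) -> BandextModel:
    config = config or CNN1dConfig()
    return BandextModel("cnn1d", CNN1d(config), config)


# ---------------------------------------------------------------------
# training


def _pairs_to_arrays(pairs, kind):
    X, Y = [], []
    for p in pairs:
        scale = np.abs(p.input_window).max()
        scale = scale if scale > 0 else 1.0
        X.append(p.input_window / scale)
        Y.append(p.target_window / scale)
    X = np.array(X, dtype=nn.DEFAULT_DTYPE)
    Y = np.array(Y, dtype=nn.DEFAULT_DTYPE)
    if kind == "unet2d":
        # windows are (window_t, window_x) -> net input (N, 1, T, X)
        return X[:, None], Y[:, None]
    # cnn1d: one example per trace, (N * window_x, 1, window_t)
    Xt = X.transpose(0, 2, 1).reshape(-1, 1, X.shape[1])
    Yt = Y.transpose(0, 2, 1).reshape(-1, 1, Y.shape[1])
    return Xt, Yt


def train(
    model: BandextModel,
    pairs: list[SamplePair],
    epochs: int = 30,
    lr: float = 1e-3,
    batch: int = 8,
    seed: int = 0,
    val_frac: float = 0.15,
) -> BandextModel:
    """Minimize window MSE with Adam; deterministic per seed.

    A fraction of the pairs is held out for validation-loss tracking.
    Loss curves land in ``model.history``; NaN loss aborts with a
    diagnostic.
    """
    if not pairs:
        raise ValueError("no training pairs")
    X, Y = _pairs_to_arrays(pairs, model.kind)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    n_val = max(1, int(val_frac * len(X))) if len(X) > 4 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    opt = nn.Adam(model.net.params(), lr=lr)
    hist = {"train": [], "val": []}
    for ep in range(epochs):
        order = rng.permutation(tr_idx)
        ep_loss, nb = 0.0, 0
        for k in range(0, len(order), batch):
            sel = order[k:k + batch]
            opt.zero_grad()
            pred = model.net.forward(X[sel], train=True)
            loss, dpred = nn.mse_loss(pred, Y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {ep}, batch {nb} (loss={loss})"
                )
            model.net.backward(dpred)
            opt.step()
            ep_loss += loss
            nb += 1
        hist["train"].append(ep_loss / max(nb, 1))
        if n_val:
            pred = model.net.forward(X[val_idx], train=False)
            vloss, _ = nn.mse_loss(pred, Y[val_idx])
            hist["val"].append(vloss)
    model.history = hist
    model.train_seed = seed
    return model


# ---------------------------------------------------------------------
# inference on full datasets


def _tile_offsets(n: int, w: int) -> list[int]:
    if n == w:
        return [0]
    stride = max(w // 2, 1)
    offs = list(range(0, n - w, stride))
    offs.append(n - w)
    return offs


def extrapolate(
    model: BandextModel,
    bandlimited: USCTDataset,
    window_t: int = 256,
    wavelet: Wavelet | None = None,
) -> USCTDataset:
    """Apply a trained model to every gather, tiling traces into
    overlapping windows blended with cosine weights along time.

    The returned dataset is labelled "extrapolated"; pass ``wavelet`` to
    attach the broadband source estimate the data now emulate.
    """
    from dataclasses import replace

    new = {}
    for key, g in bandlimited.gathers.items():
        n_t, n_x = g.traces.shape
        if n_t < window_t:
            raise ValueError(f"trace length {n_t} shorter than window {window_t}")
        out = np.zeros((n_t, n_x))
        wsum = np.zeros((n_t, 1))
        taper = (np.hanning(window_t) + 0.05)[:, None]
        for off in _tile_offsets(n_t, window_t):
            block = np.asarray(g.traces[off:off + window_t], dtype=np.float64)
            pred = model.predict_window(block)
            out[off:off + window_t] += taper * pred
            wsum[off:off + window_t] += taper[:, :1]
        out /= wsum
        new[key] = replace(g, traces=out.astype(np.float32))
    return USCTDataset(
        new, bandlimited.geometry,
        wavelet if wavelet is not None else bandlimited.wavelet,
        label="extrapolated",
    )
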
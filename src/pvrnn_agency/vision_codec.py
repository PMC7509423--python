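"""Static convolutional codec between grayscale frames and the
low-dimensional vision latent.

Encoder: three stride-1 valid convolutions halving the spatial extent
to 1x1 (kernels 33/17/16 at image size 64, scaled proportionally for
16/32), channels 1(+2 coord) -> 5 -> 15 -> 30, ReLU/ReLU/tanh, followed
by a linear+tanh projection to the latent (the 30-channel head and the
latent dimension differ, so a bridging projection is required).  The
decoder mirrors every stage with transposed convolutions.

Convolutions are built from a gather (im2col) primitive whose autodiff
adjoint is a scatter-add, so conv and conv-transpose are exact
transposes of one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, gather, scatter_add
from .optim import Adam

# kernel triplets per supported image size; spatial chain s -> s/2 -> s/4 -> 1
KERNELS = {64: (33, 17, 16), 32: (17, 9, 8), 16: (9, 5, 4)}
CHANNELS = (5, 15, 30)


@dataclass
class CodecConfig:
    image_size: int = 64
    latent_dim: int = 20
    coordconv: bool = True

    def __post_init__(self):
        if self.image_size not in KERNELS:
            raise ValueError(f"image_size must be one of {sorted(KERNELS)}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def coordconv_augment(frame: np.ndarray) -> np.ndarray:
    """Append two channels of normalized x/y pixel coordinates in [-1, 1].

    Accepts (H, W) or (B, H, W); returns (..., H, W, 3) channel-last.
    """
    frame = np.asarray(frame, dtype=np.float64)
    single = frame.ndim == 2
    if single:
        frame = frame[None]
    B, H, W = frame.shape
    ys = np.linspace(-1.0, 1.0, H)
    xs = np.linspace(-1.0, 1.0, W)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    out = np.empty((B, H, W, 3))
    out[..., 0] = frame
    out[..., 1] = xx[None]
    out[..., 2] = yy[None]
    return out[0] if single else out


def _conv_indices(H: int, W: int, C: int, k: int) -> np.ndarray:
    """im2col index array, shape (H'*W', k*k*C), into flat (H, W, C)."""
    Ho, Wo = H - k + 1, W - k + 1
    i = np.arange(Ho)[:, None, None, None, None]
    j = np.arange(Wo)[None, :, None, None, None]
    di = np.arange(k)[None, None, :, None, None]
    dj = np.arange(k)[None, None, None, :, None]
    c = np.arange(C)[None, None, None, None, :]
    idx = ((i + di) * W + (j + dj)) * C + c
    return idx.reshape(Ho * Wo, k * k * C)


class Codec:
    """Encoder/decoder pair with shared configuration."""

    def __init__(self, config: CodecConfig | None = None, seed: int = 0):
        self.config = config or CodecConfig()
        s = self.config.image_size
        ks = KERNELS[s]
        cin = 3 if self.config.coordconv else 1
        chans = (cin,) + CHANNELS
        sizes = (s, s // 2, s // 4, 1)
        rng = np.random.default_rng(seed)

        def P(fan_in, *shape):
            lim = np.sqrt(6.0 / (fan_in + shape[-1]))
            return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

        # encoder conv weights: (k*k*C_in, C_out)
        self.enc_W, self.enc_b, self.enc_idx = [], [], []
        for n, k in enumerate(ks):
            ci, co = chans[n], chans[n + 1]
            self.enc_W.append(P(k * k * ci, k * k * ci, co))
            self.enc_b.append(Tensor(np.zeros(co), requires_grad=True))
            self.enc_idx.append(_conv_indices(sizes[n], sizes[n], ci, k))
        # latent bridge 30 <-> latent_dim
        R = self.config.latent_dim
        self.W_lat = P(CHANNELS[-1], CHANNELS[-1], R)
        self.b_lat = Tensor(np.zeros(R), requires_grad=True)
        self.W_unlat = P(R, R, CHANNELS[-1])
        self.b_unlat = Tensor(np.zeros(CHANNELS[-1]), requires_grad=True)
        # decoder transposed convs: weight (C_in, k*k*C_out), mirrored chain
        dec_chans = (CHANNELS[2], CHANNELS[1], CHANNELS[0], 1)
        dec_sizes = (1, s // 4, s // 2, s)
        self.dec_W, self.dec_b, self.dec_idx, self.dec_shape = [], [], [], []
        for n, k in enumerate(reversed(ks)):
            ci, co = dec_chans[n], dec_chans[n + 1]
            self.dec_W.append(P(ci, ci, k * k * co))
            self.dec_b.append(Tensor(np.zeros(co), requires_grad=True))
            Ho = dec_sizes[n + 1]
            # scatter indices: adjoint layout of a conv over the output grid
            self.dec_idx.append(_conv_indices(Ho, Ho, co, k))
            self.dec_shape.append((Ho, Ho, co))

    # ------------------------------------------------------------------
    def parameters(self) -> list:
        out = []
        for W, b in zip(self.enc_W, self.enc_b):
            out.extend([W, b])
        out.extend([self.W_lat, self.b_lat, self.W_unlat, self.b_unlat])
        for W, b in zip(self.dec_W, self.dec_b):
            out.extend([W, b])
        return out

    # ------------------------------------------------------------------
    def _encode_t(self, frames: np.ndarray) -> Tensor:
        """(B, H, W) float frames -> (B, latent_dim) Tensor."""
        s = self.config.image_size
        x = coordconv_augment(frames) if self.config.coordconv \
            else np.asarray(frames, dtype=np.float64)[..., None]
        t = as_tensor(x.reshape(x.shape[0], -1))
        sizes = (s, s // 2, s // 4)
        for n in range(3):
            cols = gather(t, self.enc_idx[n])          # (B, P, k*k*C)
            t = cols @ self.enc_W[n] + self.enc_b[n]   # (B, P, C_out)
            t = t.tanh() if n == 2 else t.relu()
            if n < 2:
                t = t.reshape(t.shape[0], -1)
        feat = t.reshape(t.shape[0], CHANNELS[-1])      # 1x1 spatial
        return (feat @ self.W_lat + self.b_lat).tanh()

    def _decode_t(self, latent) -> Tensor:
        """(B, latent_dim) -> (B, H, W) Tensor."""
        z = as_tensor(latent)
        t = z @ self.W_unlat + self.b_unlat             # (B, 30)
        t = t.reshape(t.shape[0], 1, CHANNELS[-1])      # (B, 1 pos, C)
        for n in range(3):
            Ho, Wo, co = self.dec_shape[n]
            cols = t @ self.dec_W[n]                    # (B, P, k*k*C_out)
            t = scatter_add(cols, self.dec_idx[n], Ho * Wo * co, (Ho, Wo, co))
            t = t + self.dec_b[n]
            t = t.tanh() if n == 2 else t.relu()
            t = t.reshape(t.shape[0], Ho * Wo, co) if n < 2 else t
        s = self.config.image_size
        return t.reshape(t.shape[0], s, s)

    # ------------------------------------------------------------------
    def encode(self, frame: np.ndarray) -> np.ndarray:
        """Deterministic frame(s) -> latent(s) in (-1, 1)."""
        frame = np.asarray(frame, dtype=np.float64)
        single = frame.ndim == 2
        batch = frame[None] if single else frame
        s = self.config.image_size
        if batch.shape[1:] != (s, s):
            raise ValueError(f"expected {s}x{s} frames, got {batch.shape[1:]}")
        out = self._encode_t(batch).data
        return out[0] if single else out

    def decode(self, latent: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent, dtype=np.float64)
        single = latent.ndim == 1
        batch = latent[None] if single else latent
        if batch.shape[-1] != self.config.latent_dim:
            raise ValueError("latent dimension mismatch")
        out = self._decode_t(batch).data
        return out[0] if single else out

    # ------------------------------------------------------------------
    def save(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["image_size"] = self.config.image_size
            f.attrs["latent_dim"] = self.config.latent_dim
            f.attrs["coordconv"] = self.config.coordconv
            for i, p in enumerate(self.parameters()):
                f.create_dataset(f"p{i}", data=p.data)

    @classmethod
    def load(cls, path) -> "Codec":
        import h5py
        with h5py.File(path, "r") as f:
            cfg = CodecConfig(image_size=int(f.attrs["image_size"]),
                              latent_dim=int(f.attrs["latent_dim"]),
                              coordconv=bool(f.attrs["coordconv"]))
            codec = cls(cfg)
            for i, p in enumerate(codec.parameters()):
                p.data[...] = f[f"p{i}"][...]
        return codec


def train_codec(frames: np.ndarray, config: CodecConfig | None = None,
                epochs: int = 20, seed: int = 0, batch_size: int = 32,
                alpha: float = 0.001) -> tuple:
    """Train a codec on a frame corpus by pixel-space MSE.

    Returns (codec, history) where history maps 'train_loss'/'val_loss'
    to per-epoch lists (10% held-out validation split).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a nonempty (N, H, W) array")
    codec = Codec(config, seed=seed)
    rng = np.random.default_rng(seed)
    n = frames.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, n // 10)
    val, train = frames[perm[:n_val]], frames[perm[n_val:]]
    opt = Adam(codec.parameters(), alpha=alpha)

    def mse(batch):
        rec = codec._decode_t(codec._encode_t(batch))
        return ((rec - batch) ** 2).mean()

    history = {"train_loss": [], "val_loss": [float(mse(val).data)]}
    for _ in range(epochs):
        order = rng.permutation(train.shape[0])
        losses = []
        for lo in range(0, train.shape[0], batch_size):
            batch = train[order[lo:lo + batch_size]]
            loss = mse(batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(mse(val).data))
    return codec, history


def encode_corpus(codec: Codec, corpus: list, batch_size: int = 64) -> None:
    """Fill each PrimitiveSequence's `latents` from its frames."""
    for seq in corpus:
        if seq.frames is None:
            raise RuntimeError("sequence has no frames to encode")
        outs = [codec.encode(seq.frames[lo:lo + batch_size])
                for lo in range(0, seq.T, batch_size)]
        seq.latents = np.concatenate(outs, axis=0)
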
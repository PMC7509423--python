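"""Synthetic visuo-proprioceptive sequence generator.

Movement sequences follow a three-primitive probabilistic finite state
machine: primitive A branches to B or C (50/50 by default), and B and C
always return to A.  Each primitive segment contains three oscillation
cycles on a designated joint group; joint trajectories are smooth,
continuous across segment boundaries and normalized to [-1, 1].  Frames
are a deterministic stick-figure projection of the joint configuration
plus per-pixel Gaussian noise and a slowly drifting global brightness
term, so that vision carries substantially more noise than
proprioception.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

N_JOINTS = 16
# joint groups: 6 per arm, 4 torso/head
ARM_OSC_JOINTS = (0, 1, 6, 7)       # primitive A waves these
TORSO_JOINTS = (12, 13)             # primitives B/C rotate these
BLEND_STEPS = 4

DEFAULT_JOINT_NOISE_SD = 0.02
DEFAULT_PIXEL_NOISE_SD = 0.15


@dataclass
class PrimitiveSequence:
    labels: list
    joints: np.ndarray            # (T, 16) in [-1, 1]
    frames: np.ndarray | None     # (T, H, W) in [-1, 1]
    latents: np.ndarray | None    # (T, R_l), filled by the vision codec
    segment_len: int
    seed: int
    style: int = 0

    @property
    def T(self) -> int:
        return self.joints.shape[0]


# ----------------------------------------------------------------------
# label sampling
# ----------------------------------------------------------------------

def sample_labels(n_segments: int, seed: int, p_AB: float = 0.5) -> list:
    """Sample a primitive label sequence from the state machine.

    The machine starts in A; after A the next primitive is B with
    probability `p_AB`, else C; after B or C the next is always A.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if not 0.0 <= p_AB <= 1.0:
        raise ValueError("p_AB must be a probability")
    rng = np.random.default_rng(seed)
    labels = ["A"]
    while len(labels) < n_segments:
        if labels[-1] == "A":
            labels.append("B" if rng.random() < p_AB else "C")
        else:
            labels.append("A")
    return labels


# ----------------------------------------------------------------------
# proprioception
# ----------------------------------------------------------------------

def _style_params(style_seed: int):
    rng = np.random.default_rng(style_seed)
    amp = rng.uniform(0.55, 0.8)
    torso_amp = rng.uniform(0.5, 0.75)
    baseline = rng.uniform(-0.15, 0.15, size=N_JOINTS)
    sway_amp = rng.uniform(0.01, 0.03, size=N_JOINTS)
    return amp, torso_amp, baseline, sway_amp


def render_proprioception(labels: list, segment_len: int,
                          joint_noise_sd: float = DEFAULT_JOINT_NOISE_SD,
                          style_seed: int = 0,
                          noise_seed: int | None = None) -> np.ndarray:
    """Render labels to a (T, 16) joint trajectory in [-1, 1].

    Every segment holds exactly three oscillation cycles: primitive A on
    the designated arm joints, B/C on the torso joints with opposite
    signs.  Waveforms start and end at the per-style baseline, so the
    trajectory is continuous at segment boundaries; a short cosine-ramp
    crossfade additionally smooths the first few steps of each segment.
    """
    if segment_len < 12:
        raise ValueError("segment_len must be >= 12 (3 cycles need resolution)")
    if joint_noise_sd < 0:
        raise ValueError("joint_noise_sd must be >= 0")
    amp, torso_amp, baseline, sway_amp = _style_params(style_seed)
    L = segment_len
    t = np.arange(L)
    cycle = np.sin(2.0 * np.pi * 3.0 * t / L)       # 3 cycles per segment

    segs = []
    for lab in labels:
        seg = np.tile(baseline, (L, 1))
        seg += sway_amp[None, :] * cycle[:, None]    # small periodic sway
        if lab == "A":
            for j in ARM_OSC_JOINTS:
                seg[:, j] = baseline[j] + amp * cycle
        else:
            sign = 1.0 if lab == "B" else -1.0
            for j in TORSO_JOINTS:
                seg[:, j] = baseline[j] + sign * torso_amp * cycle
        segs.append(seg)

    # cosine-ramp crossfade from the previous segment's final value
    for i in range(1, len(segs)):
        prev_end = segs[i - 1][-1]
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(BLEND_STEPS) + 1)
                                   / (BLEND_STEPS + 1)))
        for k in range(BLEND_STEPS):
            segs[i][k] = (1.0 - ramp[k]) * prev_end + ramp[k] * segs[i][k]

    traj = np.concatenate(segs, axis=0)
    if joint_noise_sd > 0:
        rng = np.random.default_rng(
            style_seed if noise_seed is None else noise_seed)
        traj = traj + rng.normal(0.0, joint_noise_sd, size=traj.shape)
    return np.clip(traj, -1.0, 1.0)


# ----------------------------------------------------------------------
# vision
# ----------------------------------------------------------------------

SUPPORTED_IMAGE_SIZES = (16, 32, 64)


def _stick_figure(joints: np.ndarray, size: int) -> np.ndarray:
    """Deterministic nonlinear projection of one joint row to a frame.

    A torso line whose lean follows the torso joints, two arm segments
    per side driven by the arm joints, and a head blob.  Background is
    -1, strokes reach toward +1.
    """
    img = np.full((size, size), -1.0)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)  # in [0, 1]
    sw = 0.035 + 0.5 / size                         # stroke half-width

    def stroke(x0, y0, x1, y1):
        n = 24
        pts_x = np.linspace(x0, x1, n)
        pts_y = np.linspace(y0, y1, n)
        acc = np.zeros((size, size))
        for px, py in zip(pts_x, pts_y):
            acc += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * sw ** 2))
        np.maximum(img, np.clip(acc, 0.0, 1.0) * 2.0 - 1.0, out=img)

    lean = 0.35 * np.tanh(joints[12] + joints[13])
    hip = (0.5, 0.88)
    neck = (0.5 + lean * 0.5, 0.35)
    stroke(hip[0], hip[1], neck[0], neck[1])
    # head
    hx, hy = neck[0], neck[1] - 0.12
    np.maximum(img, np.clip(
        np.exp(-((xx - hx) ** 2 + (yy - hy) ** 2) / (2 * (2.2 * sw) ** 2)),
        0.0, 1.0) * 2.0 - 1.0, out=img)
    # arms: shoulder -> elbow -> hand, angles from arm joints
    for side, j0 in ((-1.0, 0), (1.0, 6)):
        sx, sy = neck[0] + side * 0.06, neck[1] + 0.05
        a1 = side * (0.5 * np.pi + 0.9 * np.tanh(joints[j0]))
        ex, ey = sx + 0.2 * np.cos(a1), sy + 0.2 * np.sin(a1)
        a2 = a1 + side * 0.9 * np.tanh(joints[j0 + 1])
        hx2, hy2 = ex + 0.18 * np.cos(a2), ey + 0.18 * np.sin(a2)
        stroke(sx, sy, ex, ey)
        stroke(ex, ey, hx2, hy2)
    return img


def render_vision(joints: np.ndarray, image_size: int = 64,
                  pixel_noise_sd: float = DEFAULT_PIXEL_NOISE_SD,
                  seed: int = 0) -> np.ndarray:
    """Render (T, 16) joints to (T, H, W) grayscale frames in [-1, 1]."""
    if image_size not in SUPPORTED_IMAGE_SIZES:
        raise ValueError(f"image_size must be one of {SUPPORTED_IMAGE_SIZES}")
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be >= 0")
    joints = np.asarray(joints, dtype=np.float64)
    T = joints.shape[0]
    frames = np.empty((T, image_size, image_size))
    for i in range(T):
        frames[i] = _stick_figure(joints[i], image_size)
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        # slow brightness drift emulating varying optical conditions,
        # plus per-frame global flicker: illumination noise is coherent
        # across pixels, so it survives the codec's spatial averaging
        phase = rng.uniform(0, 2 * np.pi)
        period = rng.uniform(60, 140)
        drift = 0.8 * pixel_noise_sd * np.sin(
            2 * np.pi * np.arange(T) / period + phase)
        flicker = rng.normal(0.0, 0.6 * pixel_noise_sd, size=T)
        frames += (drift + flicker)[:, None, None]
        frames += rng.normal(0.0, pixel_noise_sd, size=frames.shape)
    return np.clip(frames, -1.0, 1.0)


# ----------------------------------------------------------------------
# dataset assembly
# ----------------------------------------------------------------------

def build_dataset(n_sequences: int = 30, n_segments: int = 8,
                  segment_len: int = 50, seed: int = 0, n_styles: int = 3,
                  image_size: int = 64,
                  joint_noise_sd: float = DEFAULT_JOINT_NOISE_SD,
                  pixel_noise_sd: float = DEFAULT_PIXEL_NOISE_SD,
                  render_frames: bool = True) -> list:
    """Generate a corpus of PrimitiveSequence objects.

    Styles (amplitude/baseline variants emulating different human
    demonstrators) cycle over sequences.  Seed-for-seed the corpus is
    byte-identical.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if n_styles < 1:
        raise ValueError("n_styles must be >= 1")
    corpus = []
    for i in range(n_sequences):
        seq_seed = seed * 100003 + i
        style = i % n_styles
        labels = sample_labels(n_segments, seed=seq_seed)
        joints = render_proprioception(labels, segment_len, joint_noise_sd,
                                       style_seed=seed * 17 + style,
                                       noise_seed=seq_seed + 1)
        frames = None
        if render_frames:
            frames = render_vision(joints, image_size, pixel_noise_sd,
                                   seed=seq_seed + 2)
        corpus.append(PrimitiveSequence(labels=labels, joints=joints,
                                        frames=frames, latents=None,
                                        segment_len=segment_len,
                                        seed=seq_seed, style=style))
    return corpus


def manifest(corpus: list, seed: int, n_styles: int) -> dict:
    return {
        "generator_version": 1,
        "start_state": "A",
        "master_seed": seed,
        "n_styles": n_styles,
        "sequences": [
            {"index": i, "seed": s.seed, "style": s.style,
             "labels": list(s.labels), "segment_len": s.segment_len,
             "T": int(s.T)}
            for i, s in enumerate(corpus)],
    }


def save_dataset(corpus: list, out_dir, seed: int = 0, n_styles: int = 3,
                 write_hdf5: bool = False) -> None:
    """Write CSV joint tracks, PNG frames and a JSON manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = ",".join(f"j{i:02d}" for i in range(N_JOINTS))
    for i, s in enumerate(corpus):
        seq_dir = out / f"seq{i}"
        seq_dir.mkdir(exist_ok=True)
        np.savetxt(seq_dir / "joints.csv", s.joints, delimiter=",",
                   header=header, comments="")
        if s.frames is not None:
            for t in range(s.T):
                frame8 = np.round((s.frames[t] + 1.0) * 127.5).astype(np.uint8)
                iio.imwrite(seq_dir / f"frame{t:04d}.png", frame8)
    (out / "manifest.json").write_text(
        json.dumps(manifest(corpus, seed, n_styles), indent=1))
    if write_hdf5:
        import h5py
        with h5py.File(out / "dataset.h5", "w") as f:
            for i, s in enumerate(corpus):
                g = f.create_group(f"seq{i}")
                g.create_dataset("joints", data=s.joints)
                if s.frames is not None:
                    g.create_dataset("frames", data=s.frames)


def load_dataset(in_dir) -> list:
    """Read a corpus previously written by :func:`save_dataset`."""
    import imageio.v3 as iio

    src = Path(in_dir)
    man = json.loads((src / "manifest.json").read_text())
    corpus = []
    for entry in man["sequences"]:
        seq_dir = src / f"seq{entry['index']}"
        joints = np.loadtxt(seq_dir / "joints.csv", delimiter=",", skiprows=1)
        frame_files = sorted(seq_dir.glob("frame*.png"))
        frames = None
        if frame_files:
            frames = np.stack([
                np.asarray(iio.imread(f), dtype=np.float64) / 127.5 - 1.0
                for f in frame_files])
        corpus.append(PrimitiveSequence(
            labels=entry["labels"], joints=joints, frames=frames,
            latents=None, segment_len=entry["segment_len"],
            seed=entry["seed"]))
    return corpus
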
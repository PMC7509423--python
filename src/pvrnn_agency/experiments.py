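"""End-to-end experiment runners.

Experiment 1: train the network under two modality-specific meta-prior
settings (vision regulated more vs. proprioception regulated more) and
compare test-time ER metrics on held-out sequences.

Experiment 2: take one trained default model and sweep five global
meta-prior rescalings spanning four orders of magnitude during ER,
measuring how reconstruction error and KL divergence trade off (the
"strength of agency" sweep).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .error_regression import ERConfig, rescale_meta_priors, run_interaction
from .network import (NetworkConfig, PVRNN, meta_priors_w1, meta_priors_w2)
from .synthetic_data import build_dataset, manifest
from .training import TrainConfig, train
from .vision_codec import CodecConfig, encode_corpus, train_codec

SWEEP_NAMES = ("W1", "W2", "W3", "W4", "W5")


@dataclass
class ExperimentSpec:
    """Desk-scale defaults; the full-size configuration is long-running."""

    name: str = "scaled"
    out_dir: str = "scratch/experiments"
    # generator
    n_train: int = 4
    n_test: int = 2
    n_segments: int = 4
    segment_len: int = 24
    image_size: int = 16
    data_seed: int = 7
    # codec
    latent_dim: int = 8
    codec_epochs: int = 3
    # model / training
    full_size_model: bool = False
    epochs: int = 300
    n_seeds: int = 2
    # error regression
    window_len: int = 12
    er_iters: int = 12
    er_alpha: float = 0.2
    lookahead: int = 1

    @classmethod
    def full_scale(cls):
        return cls(name="full", n_train=27, n_test=3, n_segments=8,
                   segment_len=50, image_size=64, latent_dim=20,
                   codec_epochs=20, full_size_model=True, epochs=4000,
                   n_seeds=10, window_len=30, er_iters=30)

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def to_yaml(self, path):
        import yaml
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)


def _prepare_data(spec: ExperimentSpec):
    corpus = build_dataset(n_sequences=spec.n_train + spec.n_test,
                           n_segments=spec.n_segments,
                           segment_len=spec.segment_len,
                           seed=spec.data_seed, image_size=spec.image_size)
    frames = np.concatenate([s.frames for s in corpus[:spec.n_train]])
    codec, codec_hist = train_codec(
        frames, CodecConfig(image_size=spec.image_size,
                            latent_dim=spec.latent_dim),
        epochs=spec.codec_epochs, seed=spec.data_seed)
    encode_corpus(codec, corpus)
    return corpus[:spec.n_train], corpus[spec.n_train:], codec, codec_hist


def _model_cfg(spec: ExperimentSpec) -> NetworkConfig:
    if spec.full_size_model:
        cfg = NetworkConfig.default()
        cfg.l_dim = spec.latent_dim
        return cfg
    return NetworkConfig.small(l_dim=spec.latent_dim)


def _er_test(model, test_seqs, meta, spec, seed):
    cfg = ERConfig(window_len=spec.window_len, iters=spec.er_iters,
                   alpha=spec.er_alpha, meta=meta, lookahead=spec.lookahead)
    per_seq = [run_interaction(model, s, cfg, seed=seed).metrics()
               for s in test_seqs]
    return {k: float(np.mean([m[k] for m in per_seq])) for k in per_seq[0]}


def run_experiment1(spec: ExperimentSpec) -> dict:
    """Paired training under both modality settings plus ER tests."""
    out = Path(spec.out_dir) / spec.name / "exp1"
    out.mkdir(parents=True, exist_ok=True)
    train_seqs, test_seqs, codec, _ = _prepare_data(spec)
    report = {"spec": asdict(spec),
              "train_manifest": manifest(train_seqs, spec.data_seed, 3),
              "settings": {}}
    for tag, meta in (("w1", meta_priors_w1()), ("w2", meta_priors_w2())):
        runs = []
        for i in range(spec.n_seeds):
            model = PVRNN(_model_cfg(spec), seed=1000 * (i + 1))
            tcfg = TrainConfig(epochs=spec.epochs, meta=meta, seed=i,
                               log_every=max(1, spec.epochs // 50))
            model, hist, _ = train(model, train_seqs, tcfg)
            hist.to_csv(out / f"history_{tag}_seed{i}.csv")
            metrics = _er_test(model, test_seqs, meta, spec, seed=i)
            metrics["final_cost"] = hist.total[-1]
            runs.append(metrics)
        agg = {k: {"mean": float(np.mean([r[k] for r in runs])),
                   "sd": float(np.std([r[k] for r in runs]))}
               for k in runs[0]}
        report["settings"][tag] = {"per_seed": runs, "aggregate": agg}
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def run_experiment2(spec: ExperimentSpec, model: PVRNN, test_seqs: list,
                    n_er_seeds: int = 10) -> dict:
    """Five-setting meta-prior sweep on one trained default model."""
    out = Path(spec.out_dir) / spec.name / "exp2"
    out.mkdir(parents=True, exist_ok=True)
    base = meta_priors_w1()
    per_setting = {}
    for name in SWEEP_NAMES:
        meta = rescale_meta_priors(base, name)
        seeds = [_er_test(model, test_seqs, meta, spec, seed=s)
                 for s in range(n_er_seeds)]
        per_setting[name] = seeds

    # monotonicity of the sweep, per seed, over the 5 settings
    spearman = {"recon_vs_w": [], "kld_vs_w": []}
    order = np.arange(len(SWEEP_NAMES))
    for s in range(n_er_seeds):
        recon = [per_setting[n][s]["prop_error"] + per_setting[n][s]["vis_error"]
                 for n in SWEEP_NAMES]
        kld = [per_setting[n][s]["kld_total"] for n in SWEEP_NAMES]
        spearman["recon_vs_w"].append(float(stats.spearmanr(order, recon)[0]))
        spearman["kld_vs_w"].append(float(stats.spearmanr(order, kld)[0]))

    report = {
        "spec": asdict(spec),
        "per_setting": per_setting,
        "aggregate": {
            name: {k: {"mean": float(np.mean([r[k] for r in per_setting[name]])),
                       "sd": float(np.std([r[k] for r in per_setting[name]]))}
                   for k in per_setting[name][0]}
            for name in SWEEP_NAMES},
        "spearman": spearman,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
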
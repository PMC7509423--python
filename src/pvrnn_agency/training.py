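"""Offline BPTT training of the full network.

Network weights, output heads AND the per-sequence per-time-step
adaptive variables are optimized jointly with Adam (alpha=0.001,
beta1=0.9, beta2=0.999) on the meta-prior-weighted cost, full batch
over the corpus each epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .network import LAYER_NAMES, MetaPriors, PVRNN, meta_priors_w1
from .optim import Adam


@dataclass
class TrainConfig:
    epochs: int = 10000
    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    meta: MetaPriors = field(default_factory=meta_priors_w1)
    seed: int = 0
    log_every: int = 10
    clip_norm: float = 10.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class LearningHistory:
    epochs: list = field(default_factory=list)
    total: list = field(default_factory=list)
    prop_error: list = field(default_factory=list)
    vis_error: list = field(default_factory=list)
    kl: dict = field(default_factory=lambda: {n: [] for n in LAYER_NAMES})

    def append(self, epoch, total, prop, vis, kl_raw):
        self.epochs.append(epoch)
        self.total.append(total)
        self.prop_error.append(prop)
        self.vis_error.append(vis)
        for name in LAYER_NAMES:
            self.kl[name].append(kl_raw[name])

    def to_csv(self, path):
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["epoch", "total", "prop_error", "vis_error"]
                       + [f"kl_{n}" for n in LAYER_NAMES])
            for i, ep in enumerate(self.epochs):
                w.writerow([ep, self.total[i], self.prop_error[i],
                            self.vis_error[i]]
                           + [self.kl[n][i] for n in LAYER_NAMES])


def _stack_targets(dataset, model: PVRNN):
    lengths = {s.T for s in dataset}
    if len(lengths) != 1:
        raise ValueError("all sequences must have equal length (no padding)")
    p = np.stack([s.joints for s in dataset])
    if p.shape[-1] != model.cfg.p_dim:
        raise ValueError("proprioception dimension mismatch")
    for s in dataset:
        if s.latents is None:
            raise ValueError("sequence latents missing; train the codec first")
    l = np.stack([s.latents for s in dataset])
    if l.shape[-1] != model.cfg.l_dim:
        raise ValueError("vision latent dimension mismatch")
    return p, l


def train(model: PVRNN, dataset: list, cfg: TrainConfig):
    """Minimize the weighted cost over the corpus; returns (model, history, adaptive)."""
    p_target, l_target = _stack_targets(dataset, model)
    B, T, _ = p_target.shape
    adaptive = model.make_adaptive(B, T, trainable=True)
    params = model.parameters() + model.adaptive_tensors(adaptive)
    opt = Adam(params, alpha=cfg.alpha, beta1=cfg.beta1, beta2=cfg.beta2,
               clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed)
    history = LearningHistory()
    for epoch in range(cfg.epochs):
        total, comp = model.compute_cost(p_target, l_target, adaptive,
                                         cfg.meta, rng=rng)
        opt.zero_grad()
        total.backward()
        opt.step()
        if epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1:
            history.append(epoch, float(total.data),
                           float(comp["prop_error"].data),
                           float(comp["vis_error"].data),
                           comp["kl_raw"])
    return model, history, adaptive


def replicate_exp1(dataset, meta_a: MetaPriors, meta_b: MetaPriors,
                   n_inits: int, model_factory, train_cfg: TrainConfig,
                   test_fn=None):
    """Train both meta-prior settings `n_inits` times from different inits.

    `model_factory(seed)` builds a fresh network; `test_fn(model)` (optional)
    returns a dict of test-time metrics per trained model.  Returns a dict
    keyed by setting name with per-seed histories and test metrics.
    """
    report = {}
    for tag, meta in (("a", meta_a), ("b", meta_b)):
        runs = []
        for i in range(n_inits):
            model = model_factory(seed=1000 * (i + 1))
            cfg = TrainConfig(epochs=train_cfg.epochs, alpha=train_cfg.alpha,
                              beta1=train_cfg.beta1, beta2=train_cfg.beta2,
                              meta=meta, seed=train_cfg.seed + i,
                              log_every=train_cfg.log_every,
                              clip_norm=train_cfg.clip_norm)
            model, hist, _ = train(model, dataset, cfg)
            run = {"history": hist, "model": model}
            if test_fn is not None:
                run["test"] = test_fn(model)
            runs.append(run)
        report[tag] = runs
    return report
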
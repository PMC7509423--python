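"""Shifting-window error-regression (ER) inference.

With network weights frozen, a fixed-length window over the immediate
past holds per-slot adaptive variables that are re-optimized by iterated
forward/BPTT cycles at every sensory step; the window then shifts, the
oldest slot's posterior mean is committed into a cached entry state, and
a prior-mode look-ahead rollout is emitted from the window end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, add_n, sq_err
from .network import (LAYER_NAMES, MetaPriors, NetworkState, PVRNN,
                      SWEEP_SETTINGS)
from .optim import Adam
from .pvrnn_core import AdaptiveVars, LayerState


@dataclass
class ERConfig:
    window_len: int = 30
    iters: int = 30
    alpha: float = 0.2
    beta1: float = 0.9
    beta2: float = 0.999
    meta: MetaPriors = None
    lookahead: int = 1
    resample_eps: bool = False

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.iters < 0:
            raise ValueError("iters must be >= 0")
        if self.lookahead < 1:
            raise ValueError("lookahead must be >= 1")


def rescale_meta_priors(base: MetaPriors, factor) -> MetaPriors:
    """Multiply every layer's w by `factor`, or load a named sweep setting.

    Named settings ('W1'..'W5') are absolute tables spanning four orders
    of magnitude with a consistent ratio between layers; for those the
    first-step weights are set equal to the per-step weights.
    """
    if isinstance(factor, str):
        if factor not in SWEEP_SETTINGS:
            raise ValueError(f"unknown setting {factor!r}")
        w = dict(SWEEP_SETTINGS[factor])
        return MetaPriors(w=w, w1=dict(w))
    if factor <= 0:
        raise ValueError("factor must be positive")
    return base.rescaled(float(factor))


class ERWindow:
    """Rolling window state: targets, adaptive variables, entry state."""

    def __init__(self, model: PVRNN, window_len: int):
        self.model = model
        self.window_len = window_len
        state = model.initial_state(1)
        self.entry = {n: (state.layers[n].h.data.copy(),
                          state.layers[n].d.data.copy())
                      for n in LAYER_NAMES}
        self.t0 = 0                      # committed (pre-window) steps
        self.p_targets: list = []        # each (p_dim,)
        self.l_targets: list = []
        self.eps: list = []              # per slot: {layer: (1, z)}
        self.adaptive: dict = model.make_adaptive(1, 0, trainable=True)
        # refreshed by the last iteration:
        self.errors_p = np.zeros(0)
        self.errors_l = np.zeros(0)
        self.kl = {n: np.zeros(0) for n in LAYER_NAMES}
        self.end_state: NetworkState | None = None

    def __len__(self):
        return len(self.p_targets)

    # ------------------------------------------------------------------
    def _entry_state(self) -> NetworkState:
        return NetworkState(layers={
            n: LayerState(h=Tensor(self.entry[n][0]),
                          d=Tensor(self.entry[n][1]))
            for n in LAYER_NAMES}, t=self.t0)

    def _rebuild_adaptive(self, keep_from: int, extend: int):
        """Drop the first `keep_from` slots and append `extend` zero slots."""
        new = {}
        for n, cfg in self.model.cfg.layers.items():
            old_mu = self.adaptive[n].a_mu.data[:, keep_from:]
            old_sg = self.adaptive[n].a_sigma.data[:, keep_from:]
            pad = np.zeros((1, extend, cfg.z_dim))
            new[n] = AdaptiveVars(
                a_mu=Tensor(np.concatenate([old_mu, pad], axis=1),
                            requires_grad=True),
                a_sigma=Tensor(np.concatenate([old_sg, pad], axis=1),
                               requires_grad=True))
        self.adaptive = new

    def append_slot(self, p_target, l_target, rng):
        self.p_targets.append(np.asarray(p_target, dtype=np.float64))
        self.l_targets.append(np.asarray(l_target, dtype=np.float64))
        self.eps.append({n: rng.standard_normal((1, cfg.z_dim))
                         for n, cfg in self.model.cfg.layers.items()})
        self._rebuild_adaptive(0, 1)

    def commit_oldest(self, prior_mode: bool = False):
        """Retire slot 0: advance the entry state by its posterior mean."""
        state = self._entry_state()
        ad = {n: AdaptiveVars(a_mu=Tensor(self.adaptive[n].a_mu.data[:, 0]),
                              a_sigma=Tensor(self.adaptive[n].a_sigma.data[:, 0]))
              for n in LAYER_NAMES}
        mode = "prior" if prior_mode else "posterior"
        state, _ = self.model.forward_step(state, mode,
                                           None if prior_mode else ad, eps=None)
        self.entry = {n: (state.layers[n].h.data.copy(),
                          state.layers[n].d.data.copy())
                      for n in LAYER_NAMES}
        self.t0 += 1
        self.p_targets.pop(0)
        self.l_targets.pop(0)
        self.eps.pop(0)
        self._rebuild_adaptive(1, 0)


def _window_forward(model: PVRNN, window: ERWindow, meta: MetaPriors,
                    mode: str = "posterior"):
    """Forward over all slots; returns (cost, per-slot records, end state)."""
    T = len(window)
    state = window._entry_state()
    p_dim, l_dim = model.cfg.p_dim, model.cfg.l_dim
    terms = []
    err_p = np.zeros(T)
    err_l = np.zeros(T)
    kls = {n: np.zeros(T) for n in LAYER_NAMES}
    for k in range(T):
        ad = {n: AdaptiveVars(a_mu=window.adaptive[n].a_mu[:, k],
                              a_sigma=window.adaptive[n].a_sigma[:, k])
              for n in LAYER_NAMES}
        state, out = model.forward_step(
            state, mode, None if mode == "prior" else ad, eps=window.eps[k])
        ep = sq_err(out.p, window.p_targets[k][None], 1.0 / (2.0 * p_dim))
        el = sq_err(out.l, window.l_targets[k][None], 1.0 / (2.0 * l_dim))
        terms.extend([ep, el])
        err_p[k] = 2.0 * float(ep.data)
        err_l[k] = 2.0 * float(el.data)
        if mode == "posterior":
            global_t = window.t0 + k          # 0-based; 0 is sequence start
            for n in LAYER_NAMES:
                w = meta.w1[n] if global_t == 0 else meta.w[n]
                rz = model.cfg.layers[n].z_dim
                kl_sum = out.kl[n].sum()
                terms.append(kl_sum * (w / rz))
                kls[n][k] = float(kl_sum.data) / rz
    return add_n(terms), (err_p, err_l, kls), state


def er_iteration(model: PVRNN, window: ERWindow, meta: MetaPriors,
                 opt: Adam) -> ERWindow:
    """One forward/BPTT cycle updating only the adaptive variables."""
    if len(window) == 0:
        raise ValueError("window is empty")
    cost, (err_p, err_l, kls), state = _window_forward(model, window, meta)
    opt.zero_grad()
    cost.backward()
    opt.step()
    window.errors_p, window.errors_l, window.kl = err_p, err_l, kls
    window.end_state = state
    return window


def _refresh_records(model, window, meta, mode):
    _, (err_p, err_l, kls), state = _window_forward(model, window, meta, mode)
    window.errors_p, window.errors_l, window.kl = err_p, err_l, kls
    window.end_state = state


def shift_and_predict(model: PVRNN, window: ERWindow, new_obs: tuple,
                      codec, cfg: ERConfig, rng):
    """Ingest one observation, re-infer the window, emit look-ahead rollout.

    `new_obs` is (p_target, frame_or_latent); a 2-D array is treated as a
    frame and encoded (requires `codec`), a 1-D array as a ready latent.
    Returns (window, lookahead_outputs) where lookahead_outputs is the
    list of StepOutput from the prior-mode rollout past the window end.
    """
    p_t, vis = new_obs
    vis = np.asarray(vis, dtype=np.float64)
    if vis.ndim == 2:
        if codec is None:
            raise RuntimeError("a frame observation requires a trained codec")
        l_t = codec.encode(vis)
    else:
        l_t = vis
    prior_mode = cfg.iters == 0
    if len(window) == cfg.window_len:
        window.commit_oldest(prior_mode=prior_mode)
    window.append_slot(p_t, l_t, rng)

    if cfg.iters > 0:
        opt = Adam(model.adaptive_tensors(window.adaptive), alpha=cfg.alpha,
                   beta1=cfg.beta1, beta2=cfg.beta2)
        for _ in range(cfg.iters):
            if cfg.resample_eps:
                window.eps = [{n: rng.standard_normal((1, c.z_dim))
                               for n, c in model.cfg.layers.items()}
                              for _ in range(len(window))]
            er_iteration(model, window, cfg.meta, opt)
        # records/end state for the post-update adaptive values
        _refresh_records(model, window, cfg.meta, "posterior")
    else:
        _refresh_records(model, window, cfg.meta, "prior")

    state, lookahead = model.rollout(window.end_state, cfg.lookahead,
                                     mode="prior", rng=None)
    return window, lookahead


@dataclass
class InteractionTrace:
    """Per-sensory-step records of a pseudo-imitative interaction."""

    window_err_p: list = field(default_factory=list)   # mean over slots, /R^p
    window_err_l: list = field(default_factory=list)
    window_kl: dict = field(default_factory=lambda: {n: [] for n in LAYER_NAMES})
    lookahead_err_p: list = field(default_factory=list)
    lookahead_err_l: list = field(default_factory=list)
    lookahead_p: list = field(default_factory=list)    # one-step predictions
    lookahead_l: list = field(default_factory=list)

    def metrics(self) -> dict:
        """Double averages over interaction steps and window slots."""
        out = {
            "prop_error": float(np.mean(self.window_err_p)),
            "vis_error": float(np.mean(self.window_err_l)),
            "lookahead_prop_error": float(np.mean(self.lookahead_err_p))
            if self.lookahead_err_p else float("nan"),
            "lookahead_vis_error": float(np.mean(self.lookahead_err_l))
            if self.lookahead_err_l else float("nan"),
        }
        for n in LAYER_NAMES:
            out[f"kld_{n}"] = float(np.mean(self.window_kl[n]))
        out["kld_total"] = float(sum(out[f"kld_{n}"] for n in LAYER_NAMES))
        return out


def run_interaction(model: PVRNN, target, cfg: ERConfig, seed: int = 0,
                    codec=None) -> InteractionTrace:
    """Full pseudo-imitation pass over a target PrimitiveSequence.

    The counterpart's proprioception and vision-latent tracks are fed
    step by step; the executed movement is taken to equal the network's
    prediction (perfect low-level tracking).
    """
    if target.T <= cfg.window_len:
        raise ValueError("target must be longer than the ER window")
    if target.latents is None:
        if codec is None or target.frames is None:
            raise ValueError("target needs latents, or frames plus a codec")
        latents = codec.encode(target.frames)
    else:
        latents = target.latents
    rng = np.random.default_rng(seed)
    window = ERWindow(model, cfg.window_len)
    trace = InteractionTrace()
    pending = None   # prediction made at the previous step, for step t
    for t in range(target.T):
        obs = (target.joints[t], latents[t])
        if pending is not None:
            p_pred, l_pred = pending
            trace.lookahead_err_p.append(
                float(((p_pred - target.joints[t]) ** 2).sum()) / model.cfg.p_dim)
            trace.lookahead_err_l.append(
                float(((l_pred - latents[t]) ** 2).sum()) / model.cfg.l_dim)
        window, lookahead = shift_and_predict(model, window, obs, codec,
                                              cfg, rng)
        trace.window_err_p.append(float(np.mean(window.errors_p)))
        trace.window_err_l.append(float(np.mean(window.errors_l)))
        for n in LAYER_NAMES:
            trace.window_kl[n].append(float(np.mean(window.kl[n])))
        p1 = lookahead[0].p.data[0]
        l1 = lookahead[0].l.data[0]
        trace.lookahead_p.append(p1.copy())
        trace.lookahead_l.append(l1.copy())
        pending = (p1, l1)
    return trace
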
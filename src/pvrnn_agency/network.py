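"""Full multimodal network: associative core plus proprioception and
vision branches (slow + fast layers each), with same-time-step top-down
connections and meta-prior-weighted cost.

Layer graph (top-down only, no bottom-up generative links)::

              assoc (tau=15)
              /            \\
      prop_slow (8)     vis_slow (8)
          |                  |
      prop_fast (2)     vis_fast (2)
          |                  |
       p_t (16)          l_t (latent)

Each arrow is a connection from the source layer's deterministic state
at the *current* time step into the target layer's input sum.  The fast
layers drive linear+tanh output heads for the proprioception vector and
the vision latent vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, add_n, as_tensor, multi_affine, sq_err
from .pvrnn_core import (AdaptiveVars, LayerConfig, LayerParams, LayerState,
                         gaussian_kl, glorot, init_layer_params,
                         layer_params_from_dict, layer_params_to_dict,
                         leaky_update, posterior_params, prior_params,
                         reparameterize, unit_prior)

LAYER_NAMES = ("assoc", "prop_slow", "prop_fast", "vis_slow", "vis_fast")

# source of the same-time-step top-down input, per layer
TOPDOWN = {"assoc": None, "prop_slow": "assoc", "prop_fast": "prop_slow",
           "vis_slow": "assoc", "vis_fast": "vis_slow"}


@dataclass
class NetworkConfig:
    layers: dict
    p_dim: int = 16
    l_dim: int = 20

    @classmethod
    def default(cls):
        """Reference configuration: d 10/20/30/20/30, z 1/2/3/2/3, tau 15/8/2/8/2."""
        return cls(layers={
            "assoc": LayerConfig(10, 1, 15.0),
            "prop_slow": LayerConfig(20, 2, 8.0),
            "prop_fast": LayerConfig(30, 3, 2.0),
            "vis_slow": LayerConfig(20, 2, 8.0),
            "vis_fast": LayerConfig(30, 3, 2.0),
        })

    @classmethod
    def small(cls, l_dim: int = 8, p_dim: int = 16):
        """Half-width configuration for desk-scale runs."""
        return cls(layers={
            "assoc": LayerConfig(5, 1, 15.0),
            "prop_slow": LayerConfig(10, 1, 8.0),
            "prop_fast": LayerConfig(15, 2, 2.0),
            "vis_slow": LayerConfig(10, 1, 8.0),
            "vis_fast": LayerConfig(15, 2, 2.0),
        }, p_dim=p_dim, l_dim=l_dim)


@dataclass
class MetaPriors:
    """Per-layer complexity weights: `w` after the first step, `w1` at step 1."""

    w: dict
    w1: dict

    def __post_init__(self):
        for m in (self.w, self.w1):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(f"meta-prior {k} must be >= 0, got {v}")

    def rescaled(self, factor: float) -> "MetaPriors":
        if factor <= 0:
            raise ValueError("rescale factor must be positive")
        return MetaPriors(w={k: v * factor for k, v in self.w.items()},
                          w1=dict(self.w1))


def meta_priors_w1() -> MetaPriors:
    """Modality-specific setting with the vision branch more tightly regulated."""
    return MetaPriors(
        w={"assoc": 0.0025, "prop_slow": 0.005, "prop_fast": 0.01,
           "vis_slow": 0.0025, "vis_fast": 0.005},
        w1={"assoc": 0.01, "prop_slow": 0.01, "prop_fast": 0.01,
            "vis_slow": 0.05, "vis_fast": 0.05})


def meta_priors_w2() -> MetaPriors:
    """The swapped setting: proprioception regulated more than vision."""
    return MetaPriors(
        w={"assoc": 0.0025, "prop_slow": 0.0025, "prop_fast": 0.005,
           "vis_slow": 0.005, "vis_fast": 0.01},
        w1={"assoc": 0.01, "prop_slow": 0.05, "prop_fast": 0.05,
            "vis_slow": 0.01, "vis_fast": 0.01})


# five global rescalings of the default (w1-style) setting used for the
# agency sweep; ratios between layers are identical in every column
SWEEP_SETTINGS = {
    "W1": {"assoc": 2.5e-5, "prop_slow": 5.0e-5, "prop_fast": 1.0e-4,
           "vis_slow": 2.5e-5, "vis_fast": 5.0e-5},
    "W2": {"assoc": 2.5e-4, "prop_slow": 5.0e-4, "prop_fast": 1.0e-3,
           "vis_slow": 2.5e-4, "vis_fast": 5.0e-4},
    "W3": {"assoc": 2.5e-3, "prop_slow": 5.0e-3, "prop_fast": 1.0e-2,
           "vis_slow": 2.5e-3, "vis_fast": 5.0e-3},
    "W4": {"assoc": 2.5e-2, "prop_slow": 5.0e-2, "prop_fast": 1.0e-1,
           "vis_slow": 2.5e-2, "vis_fast": 5.0e-2},
    "W5": {"assoc": 2.5e-1, "prop_slow": 5.0e-1, "prop_fast": 1.0,
           "vis_slow": 2.5e-1, "vis_fast": 5.0e-1},
}


@dataclass
class NetworkState:
    layers: dict           # name -> LayerState, arrays/Tensors of shape (B, d)
    t: int = 0


@dataclass
class StepOutput:
    p: Tensor
    l: Tensor
    prior: dict
    posterior: dict | None
    z: dict
    kl: dict | None


class PVRNN:
    """The assembled generative/inference network."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.layers: dict[str, LayerParams] = {}
        for name in LAYER_NAMES:
            td = TOPDOWN[name]
            td_dim = cfg.layers[td].d_dim if td else None
            self.layers[name] = init_layer_params(cfg.layers[name], td_dim, rng)
        pf = cfg.layers["prop_fast"].d_dim
        vf = cfg.layers["vis_fast"].d_dim
        self.W_p = Tensor(glorot(rng, pf, cfg.p_dim), requires_grad=True)
        self.b_p = Tensor(np.zeros(cfg.p_dim), requires_grad=True)
        self.W_l = Tensor(glorot(rng, vf, cfg.l_dim), requires_grad=True)
        self.b_l = Tensor(np.zeros(cfg.l_dim), requires_grad=True)

    # ------------------------------------------------------------------
    def parameters(self) -> list:
        out = []
        for name in LAYER_NAMES:
            out.extend(self.layers[name].tensors())
        out.extend([self.W_p, self.b_p, self.W_l, self.b_l])
        return out

    def initial_state(self, batch: int = 1) -> NetworkState:
        # d_0 = h_0 = 0 for every sequence
        return NetworkState(layers={
            name: LayerState(h=Tensor(np.zeros((batch, cfg.d_dim))),
                             d=Tensor(np.zeros((batch, cfg.d_dim))))
            for name, cfg in self.cfg.layers.items()}, t=0)

    # ------------------------------------------------------------------
    def forward_step(self, state: NetworkState, mode: str,
                     adaptive: dict | None = None,
                     eps: dict | None = None):
        """Advance every layer one step; returns (new_state, StepOutput).

        mode='prior' samples z from the sequential prior (unit Gaussian at
        t=1); mode='posterior' samples from the adaptive-variable posterior
        and records per-layer KL(q || p).  `eps` maps layer name to a
        standard-normal draw (missing/None means zeros, i.e. mean sampling).
        """
        if mode not in ("prior", "posterior"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "posterior" and adaptive is None:
            raise RuntimeError("posterior mode requires adaptive variables")
        t = state.t + 1
        batch = as_tensor(state.layers["assoc"].d).shape[0]
        new_layers: dict[str, LayerState] = {}
        prior_d, post_d, z_d, kl_d = {}, {}, {}, {}

        for name in LAYER_NAMES:
            lcfg = self.cfg.layers[name]
            lp = self.layers[name]
            d_prev = state.layers[name].d
            if t == 1:
                prior = unit_prior(lcfg.z_dim, batch)
            else:
                prior = prior_params(d_prev, lp)
            prior_d[name] = prior
            if mode == "posterior":
                post = posterior_params(d_prev, adaptive[name], lp)
                post_d[name] = post
                dist = post
                kl_d[name] = gaussian_kl(post, prior)
            else:
                dist = prior
            e = None if eps is None else eps.get(name)
            if e is None:
                e = np.zeros((batch, lcfg.z_dim))
            z = reparameterize(dist, e)
            z_d[name] = z

            pairs = [(as_tensor(d_prev), lp.W_dd), (z, lp.W_dz)]
            td = TOPDOWN[name]
            if td is not None:
                pairs.append((new_layers[td].d, lp.W_td))
            u = multi_affine(pairs, bias=lp.b)
            h, d = leaky_update(state.layers[name].h, u, lcfg.tau)
            new_layers[name] = LayerState(h=h, d=d)

        p = multi_affine([(new_layers["prop_fast"].d, self.W_p)],
                         bias=self.b_p, act="tanh")
        l = multi_affine([(new_layers["vis_fast"].d, self.W_l)],
                         bias=self.b_l, act="tanh")
        out = StepOutput(p=p, l=l, prior=prior_d,
                         posterior=post_d if mode == "posterior" else None,
                         z=z_d, kl=kl_d if mode == "posterior" else None)
        return NetworkState(layers=new_layers, t=t), out

    # ------------------------------------------------------------------
    def rollout(self, state0: NetworkState, T: int, mode: str = "prior",
                adaptive: dict | None = None, rng=None):
        """Chain `T` forward steps.

        `adaptive` maps layer name to AdaptiveVars whose arrays have shape
        (B, T, z); `rng` is a numpy Generator for stochastic sampling, or
        None for mean (eps = 0) rollouts.
        """
        if T < 1:
            raise ValueError("T must be >= 1")
        state = state0
        outputs = []
        for k in range(T):
            eps = None
            if rng is not None:
                eps = {name: rng.standard_normal(
                    (as_tensor(state.layers[name].d).shape[0],
                     self.cfg.layers[name].z_dim))
                    for name in LAYER_NAMES}
            ad_t = None
            if adaptive is not None:
                ad_t = {name: AdaptiveVars(a_mu=adaptive[name].a_mu[:, k],
                                           a_sigma=adaptive[name].a_sigma[:, k])
                        for name in LAYER_NAMES}
            state, out = self.forward_step(state, mode, ad_t, eps)
            outputs.append(out)
        return state, outputs

    # ------------------------------------------------------------------
    def compute_cost(self, p_target, l_target, adaptive: dict,
                     meta: MetaPriors, state0: NetworkState | None = None,
                     rng=None, eps_seq: list | None = None):
        """Meta-prior-weighted negative ELBO over a batch of sequences.

        p_target: (B, T, p_dim), l_target: (B, T, l_dim).  Accuracy terms
        are 1/(2 R) squared errors; each layer's KL is weighted w/R_z
        (w1/R_z at t=1, against the unit prior).  Returns (total Tensor,
        components dict); components sum to the total.
        """
        p_target = np.asarray(p_target, dtype=np.float64)
        l_target = np.asarray(l_target, dtype=np.float64)
        B, T, pd = p_target.shape
        if pd != self.cfg.p_dim or l_target.shape[-1] != self.cfg.l_dim:
            raise ValueError("target dimensions do not match network config")
        if l_target.shape[:2] != (B, T):
            raise ValueError("proprioception/vision targets disagree in shape")
        for name in LAYER_NAMES:
            if as_tensor(adaptive[name].a_mu).shape[1] != T:
                raise ValueError("adaptive variables must cover t=1..T")
        state = state0 if state0 is not None else self.initial_state(B)

        prop_terms, vis_terms = [], []
        kl_terms = {name: [] for name in LAYER_NAMES}
        kl_raw = {name: 0.0 for name in LAYER_NAMES}
        for k in range(T):
            ad_t = {name: AdaptiveVars(a_mu=adaptive[name].a_mu[:, k],
                                       a_sigma=adaptive[name].a_sigma[:, k])
                    for name in LAYER_NAMES}
            if eps_seq is not None:
                eps = eps_seq[k]
            elif rng is not None:
                eps = {name: rng.standard_normal((B, self.cfg.layers[name].z_dim))
                       for name in LAYER_NAMES}
            else:
                eps = None
            state, out = self.forward_step(state, "posterior", ad_t, eps)
            prop_terms.append(sq_err(out.p, p_target[:, k],
                                     1.0 / (2.0 * self.cfg.p_dim)))
            vis_terms.append(sq_err(out.l, l_target[:, k],
                                    1.0 / (2.0 * self.cfg.l_dim)))
            for name in LAYER_NAMES:
                w = meta.w1[name] if k == 0 else meta.w[name]
                rz = self.cfg.layers[name].z_dim
                kl_sum = out.kl[name].sum()
                kl_terms[name].append(kl_sum * (w / rz))
                kl_raw[name] += float(kl_sum.data)

        prop_err = add_n(prop_terms)
        vis_err = add_n(vis_terms)
        kl_w = {name: add_n(kl_terms[name]) for name in LAYER_NAMES}
        total = add_n(prop_terms + vis_terms
                      + [t for name in LAYER_NAMES for t in kl_terms[name]])
        components = {
            "prop_error": prop_err,
            "vis_error": vis_err,
            "kl_weighted": kl_w,
            "kl_raw": kl_raw,
        }
        return total, components

    # ------------------------------------------------------------------
    def make_adaptive(self, batch: int, T: int, trainable: bool = True) -> dict:
        """Zero-initialized adaptive variables, shape (B, T, z) per layer."""
        return {name: AdaptiveVars(
            a_mu=Tensor(np.zeros((batch, T, cfg.z_dim)), requires_grad=trainable),
            a_sigma=Tensor(np.zeros((batch, T, cfg.z_dim)), requires_grad=trainable))
            for name, cfg in self.cfg.layers.items()}

    def adaptive_tensors(self, adaptive: dict) -> list:
        out = []
        for name in LAYER_NAMES:
            out.extend([adaptive[name].a_mu, adaptive[name].a_sigma])
        return out

    # ------------------------------------------------------------------
    def save(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["p_dim"] = self.cfg.p_dim
            f.attrs["l_dim"] = self.cfg.l_dim
            for name in LAYER_NAMES:
                g = f.create_group(name)
                lc = self.cfg.layers[name]
                g.attrs["d_dim"], g.attrs["z_dim"], g.attrs["tau"] = \
                    lc.d_dim, lc.z_dim, lc.tau
                for k, v in layer_params_to_dict(self.layers[name]).items():
                    g.create_dataset(k, data=v)
            go = f.create_group("output")
            for k, v in (("W_p", self.W_p), ("b_p", self.b_p),
                         ("W_l", self.W_l), ("b_l", self.b_l)):
                go.create_dataset(k, data=v.data)

    @classmethod
    def load(cls, path) -> "PVRNN":
        import h5py
        with h5py.File(path, "r") as f:
            layers = {}
            lcfgs = {}
            for name in LAYER_NAMES:
                g = f[name]
                lcfgs[name] = LayerConfig(int(g.attrs["d_dim"]),
                                          int(g.attrs["z_dim"]),
                                          float(g.attrs["tau"]))
                layers[name] = layer_params_from_dict(
                    {k: g[k][...] for k in g.keys()})
            cfg = NetworkConfig(layers=lcfgs,
                                p_dim=int(f.attrs["p_dim"]),
                                l_dim=int(f.attrs["l_dim"]))
            model = cls.__new__(cls)
            model.cfg = cfg
            model.layers = layers
            go = f["output"]
            model.W_p = Tensor(go["W_p"][...], requires_grad=True)
            model.b_p = Tensor(go["b_p"][...], requires_grad=True)
            model.W_l = Tensor(go["W_l"][...], requires_grad=True)
            model.b_l = Tensor(go["b_l"][...], requires_grad=True)
        return model
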
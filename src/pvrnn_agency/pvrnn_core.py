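"""Layer-level mathematics of the variational recurrent network.

A layer carries a deterministic state ``d = tanh(h)`` updated by leaky
integration with time constant ``tau``, and a stochastic latent ``z``
with a *sequential prior* ``p(z_t | d_{t-1})`` and an approximate
posterior whose heads receive per-time-step adaptive variables ``a``.
Both distributions are diagonal Gaussians with a tanh mean head and an
exp stdev head; the KL divergence between them is available in closed
form.

All operations accept either NumPy arrays or autodiff Tensors, and
return Tensors so gradients can flow during training and error
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, as_tensor, kl_diag_gaussian, leaky,
                       multi_affine, reparam)

# exp stdev heads can overflow under long BPTT; clamp keeps them sane.
SIGMA_MIN = 1e-6
SIGMA_MAX = 1e3


@dataclass
class LayerConfig:
    """Dimensions and time constant of one layer."""

    d_dim: int
    z_dim: int
    tau: float

    def __post_init__(self):
        if self.d_dim < 1 or self.z_dim < 1:
            raise ValueError("layer dimensions must be >= 1")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")


@dataclass
class GaussianParams:
    """Diagonal Gaussian (mean, stdev); arrays or Tensors, shape (..., n)."""

    mu: object
    sigma: object

    def numpy(self):
        return (as_tensor(self.mu).data, as_tensor(self.sigma).data)


@dataclass
class LayerState:
    """Pre-activation internal state h and deterministic variable d=tanh(h)."""

    h: object
    d: object


@dataclass
class AdaptiveVars:
    """Per-time-step free parameters entering the posterior heads additively."""

    a_mu: object
    a_sigma: object


@dataclass
class LayerParams:
    """All trainable arrays of one layer.

    Prior and posterior heads are distinct parameter sets; `W_td` is the
    same-time-step top-down input matrix (None for the topmost layer).
    """

    W_dd: Tensor
    W_dz: Tensor
    W_td: Tensor | None
    b: Tensor
    W_mu_p: Tensor
    b_mu_p: Tensor
    W_sigma_p: Tensor
    b_sigma_p: Tensor
    W_mu_q: Tensor
    b_mu_q: Tensor
    W_sigma_q: Tensor
    b_sigma_q: Tensor

    def tensors(self):
        out = [self.W_dd, self.W_dz, self.b,
               self.W_mu_p, self.b_mu_p, self.W_sigma_p, self.b_sigma_p,
               self.W_mu_q, self.b_mu_q, self.W_sigma_q, self.b_sigma_q]
        if self.W_td is not None:
            out.insert(2, self.W_td)
        return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def init_layer_params(cfg: LayerConfig, td_dim: int | None,
                      rng: np.random.Generator) -> LayerParams:
    """Glorot-uniform weights, zero biases."""
    d, z = cfg.d_dim, cfg.z_dim

    def P(a):
        return Tensor(a, requires_grad=True)

    return LayerParams(
        W_dd=P(glorot(rng, d, d)),
        W_dz=P(glorot(rng, z, d)),
        W_td=P(glorot(rng, td_dim, d)) if td_dim else None,
        b=P(np.zeros(d)),
        W_mu_p=P(glorot(rng, d, z)), b_mu_p=P(np.zeros(z)),
        W_sigma_p=P(glorot(rng, d, z)), b_sigma_p=P(np.zeros(z)),
        W_mu_q=P(glorot(rng, d, z)), b_mu_q=P(np.zeros(z)),
        W_sigma_q=P(glorot(rng, d, z)), b_sigma_q=P(np.zeros(z)),
    )


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def leaky_update(h_prev, u, tau: float):
    """One leaky-integrator step: h = (1-1/tau) h_prev + (1/tau) u, d = tanh(h)."""
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    h = leaky(h_prev, u, tau)
    return h, h.tanh()


def prior_params(d_prev, params: LayerParams) -> GaussianParams:
    """Sequential prior heads: mu = tanh(W d + b), sigma = exp(W d + b)."""
    d_prev = as_tensor(d_prev)
    if d_prev.shape[-1] != params.W_mu_p.shape[0]:
        raise ValueError("d_prev dimension does not match prior head")
    mu = multi_affine([(d_prev, params.W_mu_p)], bias=params.b_mu_p,
                      act="tanh")
    sigma = multi_affine([(d_prev, params.W_sigma_p)], bias=params.b_sigma_p,
                         act="exp", clip_lo=SIGMA_MIN, clip_hi=SIGMA_MAX)
    return GaussianParams(mu, sigma)


def unit_prior(z_dim: int, batch: int | None = None) -> GaussianParams:
    """N(0, I) prior used at the first time step."""
    if z_dim < 1:
        raise ValueError("z_dim must be >= 1")
    shape = (z_dim,) if batch is None else (batch, z_dim)
    return GaussianParams(Tensor(np.zeros(shape)), Tensor(np.ones(shape)))


def posterior_params(d_prev, a: AdaptiveVars, params: LayerParams) -> GaussianParams:
    """Posterior heads with additive adaptive variables inside the nonlinearity."""
    d_prev = as_tensor(d_prev)
    if d_prev.shape[-1] != params.W_mu_q.shape[0]:
        raise ValueError("d_prev dimension does not match posterior head")
    a_mu = as_tensor(a.a_mu)
    a_sigma = as_tensor(a.a_sigma)
    if a_mu.shape[-1] != params.W_mu_q.shape[1]:
        raise ValueError("adaptive variable dimension does not match z_dim")
    mu = multi_affine([(d_prev, params.W_mu_q)], bias=params.b_mu_q,
                      adds=[a_mu], act="tanh")
    sigma = multi_affine([(d_prev, params.W_sigma_q)], bias=params.b_sigma_q,
                         adds=[a_sigma], act="exp",
                         clip_lo=SIGMA_MIN, clip_hi=SIGMA_MAX)
    return GaussianParams(mu, sigma)


def reparameterize(g: GaussianParams, eps) -> Tensor:
    """z = mu + sigma * eps with eps ~ N(0, I)."""
    mu, sigma = as_tensor(g.mu), as_tensor(g.sigma)
    eps = eps.data if isinstance(eps, Tensor) else np.asarray(eps, dtype=np.float64)
    if eps.shape[-1] != mu.shape[-1]:
        raise ValueError("eps dimension does not match z dimension")
    return reparam(mu, sigma, eps)


def gaussian_kl(q: GaussianParams, p: GaussianParams) -> Tensor:
    """Closed-form KL(q || p) of two diagonal Gaussians, summed over dims.

    sum_i ln(sigma_p/sigma_q) + ((mu_p - mu_q)^2 + sigma_q^2) / (2 sigma_p^2) - 1/2
    """
    mu_q, sg_q = as_tensor(q.mu), as_tensor(q.sigma)
    mu_p, sg_p = as_tensor(p.mu), as_tensor(p.sigma)
    if mu_q.shape[-1] != mu_p.shape[-1]:
        raise ValueError("dimension mismatch between q and p")
    if np.any(sg_q.data <= 0) or np.any(sg_p.data <= 0):
        raise ValueError("sigma must be positive")
    return kl_diag_gaussian(mu_q, sg_q, mu_p, sg_p)


# ----------------------------------------------------------------------
# checkpoint helpers (HDF5 round-trip is handled at the network level)
# ----------------------------------------------------------------------

_FIELDS = ("W_dd", "W_dz", "W_td", "b", "W_mu_p", "b_mu_p", "W_sigma_p",
           "b_sigma_p", "W_mu_q", "b_mu_q", "W_sigma_q", "b_sigma_q")


def layer_params_to_dict(p: LayerParams) -> dict:
    out = {}
    for f in _FIELDS:
        v = getattr(p, f)
        if v is not None:
            out[f] = v.data.copy()
    return out


def layer_params_from_dict(d: dict) -> LayerParams:
    kw = {f: (Tensor(d[f], requires_grad=True) if f in d else None)
          for f in _FIELDS}
    return LayerParams(**kw)
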
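"""Geometry of pleiotropy: focal-trait effect sizes given selection.

All mutations with selection coefficient ``s`` lie on a hypersphere of
radius ``a = w*sqrt(s)`` in n-dimensional trait space; isotropic mutation
makes them uniform on that sphere.  The focal-trait effect ``a1`` is the
projection onto the first axis, with density proportional to the volume of
the (n-2)-dimensional cross-section:

    phi_n(a1 | a)  ∝  (1 - a1**2/a**2)**((n-3)/2)   on (-a, a),

normalized so the second moment is E(a1**2 | s) = a**2/n = (w**2/n) s.
As n grows, a1 / sqrt(a**2/n) -> N(0, 1) (the pleiotropic limit), already
accurate for moderate n (~10).  The case n = 1 is discrete (a1 = ±a with
probability 1/2 each) and is handled as a separate code path, never as a
density.

The canonical internal representation is the *scaled squared effect*

    eps = n * a1**2 / a**2,   so that   a1**2 = (w**2/n) * s * eps,

with E(eps) = 1.  Exactly, eps/n ~ Beta(1/2, (n-1)/2); in the pleiotropic
limit eps ~ chi-square with 1 df.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import betainc, gammaln

from .model import ModelParams, SelectionCoefficient

__all__ = [
    "effect_density",
    "effect_cdf",
    "sample_effect",
    "sample_eps",
    "eps_survival",
    "conditional_second_moment",
]

_MODES = ("pleiotropic-limit", "exact-n")


def effect_density(a1, a: float, n: float):
    """Density phi_n(a1 | a) of the focal-trait effect for n > 1.

    Vanishes outside (-a, a).  For n = 1 the conditional law is the
    two-point mass at ±a and has no density; that path raises.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        raise ValueError(
            "n = 1 is discrete: a1 = ±a with probability 1/2 each "
            "(use sample_effect or the point-mass form directly)"
        )
    if not a > 0:
        raise ValueError(f"a must be positive, got {a}")
    a1 = np.asarray(a1, dtype=float)
    x = a1 / a
    # log normalizer: 1 / (a * B(1/2, (n-1)/2))
    log_norm = gammaln(n / 2) - gammaln((n - 1) / 2) - 0.5 * np.log(np.pi) - np.log(a)
    inside = np.abs(x) < 1
    out = np.zeros_like(a1, dtype=float)
    expo = (n - 3) / 2.0
    with np.errstate(divide="ignore"):
        out[inside] = np.exp(log_norm + expo * np.log1p(-x[inside] ** 2))
    return out if out.ndim else float(out)


def effect_cdf(a1, a: float, n: float):
    """CDF of phi_n, via the regularized incomplete beta function."""
    if n <= 1:
        raise ValueError("effect_cdf requires n > 1")
    a1 = np.asarray(a1, dtype=float)
    x = np.clip(a1 / a, -1.0, 1.0)
    ib = betainc(0.5, (n - 1) / 2.0, x**2)
    out = 0.5 + 0.5 * np.sign(x) * ib
    return out if out.ndim else float(out)


def sample_eps(n_traits: float, size: int, rng: np.random.Generator,
               mode: str = "pleiotropic-limit") -> np.ndarray:
    """Draw the scaled squared effect eps = n*a1**2/a**2, E(eps) = 1."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == "pleiotropic-limit":
        return rng.chisquare(1, size)
    if n_traits == 1:
        return np.ones(size)
    return n_traits * rng.beta(0.5, (n_traits - 1) / 2.0, size)


def eps_survival(x, n_traits: float | None = None,
                 mode: str = "pleiotropic-limit"):
    """P(eps > x) for the scaled squared effect distribution."""
    x = np.asarray(x, dtype=float)
    if mode == "pleiotropic-limit":
        return stats.chi2.sf(x, df=1)
    if n_traits == 1:
        return (x < 1.0).astype(float)
    return stats.beta.sf(x / n_traits, 0.5, (n_traits - 1) / 2.0)


def sample_effect(s: SelectionCoefficient | float, params: ModelParams,
                  rng: np.random.Generator | int, size: int = 1,
                  mode: str = "pleiotropic-limit") -> np.ndarray:
    """Draw focal-trait effects a1 conditional on the selection coefficient.

    In ``pleiotropic-limit`` mode a1 ~ N(0, (w**2/n) s); in ``exact-n``
    mode a1 = ±a*sqrt(eps/n) with eps/n ~ Beta(1/2, (n-1)/2) (for n = 1
    this is exactly ±w*sqrt(s) with equal probability).
    """
    if isinstance(s, SelectionCoefficient):
        s = s.s
    if s < 0:
        raise ValueError("s must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if s == 0:
        return np.zeros(size)
    a = params.w * np.sqrt(s)
    if mode == "pleiotropic-limit":
        return rng.normal(0.0, a / np.sqrt(params.n), size)
    eps = sample_eps(params.n, size, rng, mode=mode)
    signs = rng.choice([-1.0, 1.0], size)
    return signs * a * np.sqrt(eps / params.n)


def conditional_second_moment(s: SelectionCoefficient | float,
                              params: ModelParams) -> float:
    """E(a1**2 | s) = (w**2/n) s, identical in every parameterization."""
    if isinstance(s, SelectionCoefficient):
        s = s.s
    return params.w**2 / params.n * s
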
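"""Equilibrium genetic architecture from diffusion theory.

A new mutation with scaled selection coefficient ``S = 2Ns`` enters at
frequency ``q0 = 1/2N`` and drifts under the underdominant dynamics of
stabilizing selection with the population mean at the optimum:

    M(q) = s * p*q*(q - 1/2)        (drift; vanishes at q = 1/2)
    V(q) = p*q / 2N                 (genetic drift),  p = 1 - q.

The expected time the mutation spends at each frequency before absorption
(the sojourn-time density ``t(q)``) follows from standard diffusion
theory with scale density psi(y) = exp(S*y*(1-y)):

    t(q) = 2 * [int_0^q0 psi] * [int_q^1 psi]
           / (V(q) * psi(q) * int_0^1 psi)      for q >= q0,

and the mirrored form below q0.  Because psi integrates in closed form
via the error function, everything here reduces to stable erfc/log-erfc
expressions plus one-dimensional quadrature.

All variance statistics are reported per new mutation in units of
``v_s = 2w**2/(nN)``; multiplying by the influx 2Nu converts to
stationary per-site moments.  The contribution of a site in these units
is ``v = (S/2) * eps * q * (1-q)`` with eps the scaled squared effect
(see :mod:`quantgen_arch.pleiotropy`), which makes every curve here a
function of (S, n) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import cumulative_trapezoid, quad
from scipy.special import betaln, erf, exp1, log_ndtr

from .model import ModelParams
from .pleiotropy import eps_survival, sample_eps

__all__ = [
    "SojournDensity",
    "ArchitectureCurve",
    "sojourn_density",
    "pq_sojourn",
    "drift_coefficient",
    "diffusion_coefficient",
    "variance_integral",
    "expected_variance_per_site",
    "variance_ratio_curve",
    "maf_variance_fraction",
    "G_closed",
    "G_numeric",
    "expected_sites_above",
    "sites_above_per_mutation",
    "sites_above_strong_limit",
    "regime_for",
    "REGIMES",
]

REGIMES = ("strong-n1", "neutral-n1", "strong-limit", "neutral-limit")

_DEFAULT_N = 10_000
_LN2 = np.log(2.0)
_SQRT2 = np.sqrt(2.0)


def drift_coefficient(q, s: float):
    """Per-generation E(dq) = s*p*q*(q - 1/2)."""
    q = np.asarray(q, dtype=float)
    return s * q * (1 - q) * (q - 0.5)


def diffusion_coefficient(q, N: int):
    """Per-generation V(dq) = p*q/2N."""
    q = np.asarray(q, dtype=float)
    return q * (1 - q) / (2 * N)


def _log_erfc(x):
    return _LN2 + log_ndtr(-np.asarray(x, dtype=float) * _SQRT2)


def _log_pq_t(q, S: float, N: int, q0: float):
    """log of q*(1-q)*t(q), vectorized over q, for S > 0.

    Derivation: with psi(y) = exp(S*y*(1-y)) the scale integral is
    Psi(x) = C*[erf(sqrt(S)*(x-1/2)) + erf(sqrt(S)/2)], and the sojourn
    formula collapses (q >= q0 branch) to

      pq*t(q) = N*sqrt(pi/S) * [erfc(x0)-erfc(c)] * [erfc(z)-erfc(c)]
                * exp(z**2) / erf(c),

    with c = sqrt(S)/2, z = sqrt(S)*(q-1/2), x0 = sqrt(S)*(1/2-q0).
    The q < q0 branch swaps the roles of the boundaries.  Everything is
    evaluated in log space so arbitrarily strong selection is safe.
    """
    q = np.asarray(q, dtype=float)
    rS = np.sqrt(S)
    c = rS / 2.0
    lc = _log_erfc(c)
    log_erf_c = np.log(erf(c)) if c > 1e-8 else np.log(2 * c / np.sqrt(np.pi))
    z = rS * (q - 0.5)
    lead = np.log(N) + 0.5 * np.log(np.pi / S) - log_erf_c + z**2

    # branch q >= q0
    x0 = rS * (0.5 - q0)
    la_hi = _stable_log_diff(_log_erfc(x0), lc)
    lb_hi = _stable_log_diff(_log_erfc(z), lc)
    # branch q < q0 (mirrored)
    z0 = rS * (q0 - 0.5)
    la_lo = _stable_log_diff(_log_erfc(z0), lc)
    lb_lo = _stable_log_diff(_log_erfc(-z), lc)

    hi = q >= q0
    return lead + np.where(hi, la_hi + lb_hi, la_lo + lb_lo)


def _stable_log_diff(la, lb):
    """log(exp(la) - exp(lb)) for la > lb, elementwise-stable."""
    la = np.asarray(la, dtype=float)
    with np.errstate(invalid="ignore"):
        out = la + np.log1p(-np.exp(np.minimum(lb - la, -1e-300)))
    return out


def pq_sojourn(q, S: float, N: int = _DEFAULT_N, q0: float | None = None):
    """q*(1-q)*t(q): the sojourn density weighted by heterozygosity/2.

    This is the integrand of every variance statistic; the drift-variance
    factor q(1-q) cancels the same factor in V(q), so it is smooth and
    bounded on (0, 1).
    """
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie strictly inside (0, 1)")
    if q0 is None:
        q0 = 1.0 / (2 * N)
    if S == 0:
        out = np.where(q >= q0, 4 * N * q0 * (1 - q), 4 * N * (1 - q0) * q)
    else:
        out = np.exp(_log_pq_t(q, S, N, q0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SojournDensity:
    """Expected time t(q) at frequency q per new mutation (generations)."""

    S: float
    N: int
    q: np.ndarray
    t: np.ndarray

    def total_time(self) -> float:
        """Expected total segregation time, int t(q) dq."""
        return float(np.trapezoid(self.t, self.q))


def _default_q_grid(N: int, m: int = 4000) -> np.ndarray:
    q0 = 1.0 / (2 * N)
    edge = np.geomspace(q0, 0.05, m // 3)
    mid = np.linspace(0.05, 0.95, m // 3)
    return np.unique(np.concatenate([edge, mid, 1.0 - edge[::-1]]))


def sojourn_density(S: float, N: int = _DEFAULT_N,
                    q_grid: np.ndarray | None = None) -> SojournDensity:
    """Sojourn-time density of a new mutation entering at q0 = 1/2N."""
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    if N < 100:
        raise ValueError(f"N must be >= 100 for the diffusion scaling, got {N}")
    q = _default_q_grid(N) if q_grid is None else np.asarray(q_grid, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q_grid must lie strictly inside (0, 1)")
    t = pq_sojourn(q, S, N) / (q * (1 - q))
    return SojournDensity(S=float(S), N=int(N), q=q, t=t)


def variance_integral(S: float, N: int = _DEFAULT_N) -> float:
    """int p*q*t(q) dq over (q0, 1-q0): expected time-integrated
    heterozygosity/2 per new mutation.  Equals ~1 for S = 0 and ~2/S for
    strong selection."""
    q0 = 1.0 / (2 * N)
    val, _ = quad(lambda q: pq_sojourn(q, S, N), q0, 1 - q0,
                  limit=400, epsabs=1e-13, epsrel=1e-10)
    return val


def expected_variance_per_site(S: float, params: ModelParams | None = None,
                               N: int | None = None) -> float:
    """Expected per-new-mutation contribution to genetic variance, in v_s.

    E(2*a1**2*p*q | S) factorizes as E(a1**2|S) * E(2pq|S); in v_s units
    this is (S/2) * int p*q*t(q) dq.  Tends to 1 as S -> inf (each strong
    site contributes v_s) and to S/2 as S -> 0.
    """
    if N is None:
        N = params.N if params is not None else _DEFAULT_N
    if S == 0:
        return 0.0
    return 0.5 * S * variance_integral(S, N)


def variance_ratio_curve(S_grid, params: ModelParams | None = None,
                         N: int | None = None) -> pd.DataFrame:
    """Per-S expected variance (units of v_s) plus the landmarks of the
    curve: where it crosses 1 and where it peaks.

    Returns a DataFrame (S, ratio) whose ``attrs`` carry ``crossing``
    (ratio = 1), ``argmax`` and ``peak``.
    """
    S_grid = np.asarray(S_grid, dtype=float)
    if S_grid.ndim != 1 or S_grid.size < 2 or np.any(np.diff(S_grid) <= 0):
        raise ValueError("S_grid must be a sorted 1-D grid")
    if np.any(S_grid <= 0):
        raise ValueError("S_grid must be positive")
    if N is None:
        N = params.N if params is not None else _DEFAULT_N
    ratios = np.array([expected_variance_per_site(S, N=N) for S in S_grid])
    df = pd.DataFrame({"S": S_grid, "ratio": ratios})

    f = lambda S: expected_variance_per_site(S, N=N)
    # crossing of 1 (bracket from the grid if possible, else the known range)
    lo, hi = 1.0, 8.0
    below = np.where(ratios < 1)[0]
    above = np.where(ratios > 1)[0]
    if below.size and above.size and below[0] < above[0]:
        lo, hi = S_grid[below[below < above[0]][-1]], S_grid[above[0]]
    crossing = optimize.brentq(lambda S: f(S) - 1.0, lo, hi, xtol=1e-8)
    res = optimize.minimize_scalar(
        lambda lS: -f(np.exp(lS)),
        bounds=(np.log(max(crossing, 1.0)), np.log(60.0)),
        method="bounded", options={"xatol": 1e-9},
    )
    df.attrs["crossing"] = float(crossing)
    df.attrs["argmax"] = float(np.exp(res.x))
    df.attrs["peak"] = float(-res.fun)
    return df


def maf_variance_fraction(S: float, maf0: float, N: int = _DEFAULT_N) -> float:
    """Fraction of additive variance from sites with MAF > maf0.

    MAF folds q and 1-q; the fold is applied to the integration region of
    the variance-weighted sojourn density, not to the stored frequencies.
    """
    if not 0 <= maf0 < 0.5:
        raise ValueError(f"maf0 must be in [0, 1/2), got {maf0}")
    if maf0 == 0:
        return 1.0
    q0 = 1.0 / (2 * N)
    num, _ = quad(lambda q: pq_sojourn(q, S, N), max(maf0, q0),
                  min(1 - maf0, 1 - q0), limit=400, epsabs=1e-13, epsrel=1e-10)
    return num / variance_integral(S, N)


# ---------------------------------------------------------------------------
# Distribution of variances among segregating sites, G(v)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureCurve:
    """G(v): fraction of additive variance from sites contributing > v
    (v in units of v_s), with the regime the curve was computed in."""

    v: np.ndarray
    G: np.ndarray
    regime: str
    S: float | None = None
    n: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"v": self.v, "G": self.G})
        df["regime"] = self.regime
        if self.S is not None:
            df["S"] = self.S
        return df

    def __call__(self, v):
        return np.interp(v, self.v, self.G)


def regime_for(S: float, n: float | None = None) -> str:
    """Closed-form regime for auto-selection: strong above S=30, neutral
    below S=1, numeric in between."""
    tag = "n1" if n == 1 else "limit"
    if S > 30:
        return f"strong-{tag}"
    if S < 1:
        return f"neutral-{tag}"
    return "numeric"


def G_closed(v, S: float | None = None, regime: str = "strong-limit"):
    """Closed forms of G(v) in the four regime corners (v in v_s units).

    strong-n1      exp(-2v)
    neutral-n1     sqrt(1 - v/v_max), v_max = S/8 (zero beyond v_max)
    strong-limit   (1 + 2*sqrt(v)) * exp(-2*sqrt(v))
    neutral-limit  exp(-4v/S)
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("v must be >= 0")
    if regime == "strong-n1":
        out = np.exp(-2 * v)
    elif regime == "neutral-n1":
        if S is None or S <= 0:
            raise ValueError("neutral-n1 requires S > 0")
        vmax = S / 8.0
        out = np.sqrt(np.clip(1 - v / vmax, 0.0, 1.0))
    elif regime == "strong-limit":
        r = np.sqrt(v)
        out = (1 + 2 * r) * np.exp(-2 * r)
    elif regime == "neutral-limit":
        if S is None or S <= 0:
            raise ValueError("neutral-limit requires S > 0")
        out = np.exp(-4 * v / S)
    else:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    return out if out.ndim else float(out)


class _PQSojournTable:
    """Cumulative int pq*t dq on a dense grid, for fast region integrals."""

    def __init__(self, S: float, N: int, m: int = 6000):
        self.q = _default_q_grid(N, m)
        w = pq_sojourn(self.q, S, N)
        self.W = np.concatenate([[0.0], cumulative_trapezoid(w, self.q)])
        self.total = float(self.W[-1])
        self.S = S

    def between(self, qlo, qhi):
        qlo = np.clip(qlo, self.q[0], self.q[-1])
        qhi = np.clip(qhi, self.q[0], self.q[-1])
        return np.interp(qhi, self.q, self.W) - np.interp(qlo, self.q, self.W)

    def region_mass(self, thr):
        """int pq*t dq over { q : q(1-q) > thr }, vectorized over thr."""
        thr = np.asarray(thr, dtype=float)
        d = np.sqrt(np.clip(0.25 - thr, 0.0, None))
        out = self.between(0.5 - d, 0.5 + d)
        return np.where(thr < 0.25, out, 0.0)


def _eps_quadrature(n: float | None, mode: str, m: int = 1500):
    """Nodes eps_j and weights w_j with sum w_j ~ 1 = E-weighting measure
    for the scaled squared effect; weights carry the density."""
    if mode == "pleiotropic-limit":
        # eps = x**2, x half-normal: measure sqrt(2/pi) exp(-x^2/2) dx
        x = np.linspace(1e-9, 8.5, m)
        wts = np.sqrt(2 / np.pi) * np.exp(-x**2 / 2)
        return x**2, wts, x
    if n == 1:
        return np.array([1.0]), np.array([1.0]), None
    # eps = n*sin(theta)^2, sin^2(theta) ~ Beta(1/2,(n-1)/2); the theta
    # substitution removes the u^(-1/2) endpoint singularity.
    theta = np.linspace(1e-7, np.pi / 2 - 1e-7, m)
    lognorm = -betaln(0.5, (n - 1) / 2.0)
    wts = 2 * np.exp(lognorm) * np.cos(theta) ** (n - 2)
    return n * np.sin(theta) ** 2, wts, theta


def _trapz_weights(x):
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2
    w[0] = (x[1] - x[0]) / 2
    w[-1] = (x[-1] - x[-2]) / 2
    return w


def G_numeric(v_grid, S: float, params: ModelParams | None = None,
              n: float | None = None, N: int | None = None,
              mode: str = "pleiotropic-limit", method: str = "quadrature",
              mc_size: int = 200_000, seed=None) -> ArchitectureCurve:
    """Numeric G(v) for any (S, n): the oracle behind the closed forms.

    Integrates the variance-weighted survival of v = (S/2)*eps*q*(1-q)
    over the joint law of q (sojourn-weighted) and eps (effect geometry),
    either by nested quadrature (default) or Monte Carlo.
    """
    import warnings as _warnings

    v_grid = np.asarray(v_grid, dtype=float)
    if np.any(v_grid < 0):
        raise ValueError("v_grid must be >= 0")
    if N is None:
        N = params.N if params is not None else _DEFAULT_N
    if n is None and params is not None:
        n = params.n
    if mode == "exact-n" and n is None:
        raise ValueError("exact-n mode requires n")
    if S <= 0:
        raise ValueError("G_numeric requires S > 0")

    if method == "mc":
        if mc_size < 10_000:
            _warnings.warn(f"mc_size = {mc_size} < 1e4: noisy oracle", stacklevel=2)
        rng = np.random.default_rng(seed)
        dens = sojourn_density(S, N, _default_q_grid(N, 6000))
        cdf = np.concatenate([[0.0], cumulative_trapezoid(dens.t, dens.q)])
        cdf /= cdf[-1]
        q = np.interp(rng.random(mc_size), cdf, dens.q)
        eps = sample_eps(n if n is not None else np.inf, mc_size, rng, mode=mode)
        v = 0.5 * S * eps * q * (1 - q)
        tot = v.sum()
        G = np.array([v[v > v0].sum() / tot for v0 in v_grid])
    elif method == "quadrature":
        table = _PQSojournTable(S, N)
        eps, wts, x = _eps_quadrature(n, mode)
        if eps.size == 1:  # n = 1: eps is the point mass at 1
            num = table.region_mass(2 * v_grid / S)
        else:
            dx = _trapz_weights(x)
            thr = 2 * v_grid[None, :] / (S * eps[:, None])
            P = table.region_mass(thr.ravel()).reshape(thr.shape)
            num = np.einsum("j,j,j,ji->i", eps, wts, dx, P)
        den = table.total  # E(eps) = 1 in both parameterizations
        G = num / den
    else:
        raise ValueError(f"method must be 'quadrature' or 'mc', got {method!r}")

    G = np.clip(G, 0.0, 1.0)
    G[v_grid == 0] = 1.0
    return ArchitectureCurve(v=v_grid, G=G, regime="numeric", S=S, n=n)


# ---------------------------------------------------------------------------
# Numbers of segregating sites above a variance threshold
# ---------------------------------------------------------------------------

def sites_above_per_mutation(v, S: float, n: float | None = None,
                             N: int = _DEFAULT_N,
                             mode: str = "pleiotropic-limit") -> np.ndarray:
    """Expected time (generations) a new mutation spends segregating with
    contribution > v (v in v_s units): int t(q) P(eps > 2v/(S q(1-q))) dq.

    Multiplying by the influx 2Nu gives the stationary expected number of
    segregating sites per target site above v.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    q = _default_q_grid(N, 6000)
    t = pq_sojourn(q, S, N) / (q * (1 - q))
    dq = _trapz_weights(q)
    thr = 2 * v[:, None] / (S * q[None, :] * (1 - q[None, :]))
    surv = eps_survival(thr.ravel(), n, mode=mode).reshape(thr.shape)
    out = surv @ (t * dq)
    return out if out.size > 1 else float(out[0])


def expected_sites_above(v, S: float, n: float | None = None,
                         params: ModelParams | None = None,
                         N: int | None = None, u: float | None = None,
                         mode: str = "pleiotropic-limit"):
    """Expected number of segregating sites per target site whose
    contribution to variance exceeds v (v in v_s units): 2Nu times the
    per-mutation sojourn count."""
    if params is not None:
        N = params.N if N is None else N
        u = params.u if u is None else u
    if N is None or u is None:
        raise ValueError("need params or explicit (N, u)")
    return 2 * N * u * sites_above_per_mutation(v, S, n=n, N=N, mode=mode)


def sites_above_strong_limit(v, n: float | None = None,
                             mode: str = "pleiotropic-limit") -> np.ndarray:
    """Strong-selection limit of the per-mutation sojourn count above v.

    For strong S, p*q*t(q) -> 2*exp(-S*q) and the count above v becomes
    E_eps[2*E1(2*v/eps)], independent of S (v in v_s units).  E1 is the
    exponential integral.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if np.any(v <= 0):
        raise ValueError("strong-limit site count requires v > 0 "
                         "(the count diverges logarithmically at v = 0)")
    eps, wts, x = _eps_quadrature(n, mode)
    if eps.size == 1:
        out = 2 * exp1(2 * v)
    else:
        dx = _trapz_weights(x)
        e1 = exp1(2 * v[None, :] / eps[:, None])
        out = 2 * np.einsum("j,j,ji->i", wts, dx, e1)
    return out if out.size > 1 else float(out[0])
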
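"""Wright-Fisher forward simulation under stabilizing selection.

Two levels of resolution:

* :func:`simulate_site` / :func:`variance_by_s_under_demography` follow
  single-site allele-frequency trajectories under the marginal
  underdominant drift E(dq) = s*p*q*(q-1/2) with binomial resampling,
  for an arbitrary piecewise population-size history.  This is the
  workhorse for studying how bottlenecks and growth reshape the
  distribution of variances among sites.

* :func:`simulate_multilocus` is a small individual-based simulation of
  the full model (Gaussian fitness over n traits, Poisson mutation, free
  recombination).  It exists to validate the single-site reduction: that
  the population mean sits at the optimum, phenotypes are normal, and
  per-site frequency changes follow the marginal drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelParams
from .architecture import sojourn_density, variance_integral
from .pleiotropy import sample_eps

__all__ = [
    "Epoch",
    "Demography",
    "TrajectoryEnsemble",
    "simulate_site",
    "variance_by_s_under_demography",
    "simulate_multilocus",
]

# |E(dq)| = s*|pq(q-1/2)| peaks at q = (1 ± 1/sqrt(3))/2
_MAX_PQQH = 1.0 / (12.0 * np.sqrt(3.0))


@dataclass(frozen=True)
class Epoch:
    """One piece of a population-size history.

    Constant size when ``N_end`` is None; otherwise exponential
    interpolation from ``N_start`` to ``N_end`` over ``gens``
    generations, discretized per generation (rounded, floored at 2).
    """

    gens: int
    N_start: int
    N_end: int | None = None
    mode: str = "constant"

    def __post_init__(self):
        if self.gens <= 0:
            raise ValueError("epoch duration must be > 0 generations")
        if self.N_start < 2 or (self.N_end is not None and self.N_end < 2):
            raise ValueError("population sizes must be >= 2")
        if self.mode not in ("constant", "exp"):
            raise ValueError(f"unknown epoch mode {self.mode!r}")

    def sizes(self) -> np.ndarray:
        if self.mode == "constant" or self.N_end is None:
            return np.full(self.gens, int(self.N_start), dtype=np.int64)
        t = np.arange(self.gens, dtype=float)
        rate = np.log(self.N_end / self.N_start) / self.gens
        out = np.rint(self.N_start * np.exp(rate * (t + 1))).astype(np.int64)
        return np.maximum(out, 2)


@dataclass(frozen=True)
class Demography:
    """Piecewise population-size history N(t), oldest epoch first."""

    epochs: tuple

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("demography needs at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @classmethod
    def constant(cls, N: int, gens: int) -> "Demography":
        return cls(epochs=(Epoch(gens=gens, N_start=N),))

    @classmethod
    def from_dict(cls, raw: dict) -> "Demography":
        eps = []
        for e in raw["epochs"]:
            if "N" in e:
                eps.append(Epoch(gens=int(e["gens"]), N_start=int(e["N"])))
            else:
                eps.append(Epoch(gens=int(e["gens"]), N_start=int(e["N_start"]),
                                 N_end=int(e["N_end"]),
                                 mode=e.get("mode", "exp")))
        return cls(epochs=tuple(eps))

    def sizes(self) -> np.ndarray:
        """N(t) for t = 0 .. total_gens-1 (the present is the last entry)."""
        return np.concatenate([e.sizes() for e in self.epochs])

    @property
    def total_gens(self) -> int:
        return int(sum(e.gens for e in self.epochs))


@dataclass
class TrajectoryEnsemble:
    """Outcome of replicate single-site trajectories."""

    s: float
    origin: np.ndarray          # generation index at which each mutation arose
    final_q: np.ndarray         # frequency at the present (0 = lost, 1 = fixed)
    sum_pq: np.ndarray          # time-integrated q(1-q) per replicate
    eps: np.ndarray             # scaled squared effect per replicate
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def segregating(self) -> np.ndarray:
        return (self.final_q > 0) & (self.final_q < 1)

    def variance_contribution(self, params: ModelParams) -> np.ndarray:
        """2*a1**2*p*q at the present per replicate (raw trait units);
        zero for lost/fixed replicates."""
        a1sq = params.w**2 / params.n * self.s * self.eps
        return 2 * a1sq * self.final_q * (1 - self.final_q)


def _check_s(s: float):
    if s < 0:
        raise ValueError("s must be >= 0")
    if s * _MAX_PQQH > 0.5:
        raise ValueError(
            f"s = {s:.3g} implies |E(dq)| > 0.5: too strong for the "
            "discrete Wright-Fisher update"
        )


def simulate_site(s: float, demography: Demography,
                  origin_policy: str = "uniform-influx",
                  n_reps: int = 10_000, seed=None,
                  params: ModelParams | None = None,
                  eps_mode: str = "pleiotropic-limit",
                  max_gens: int | None = None) -> TrajectoryEnsemble:
    """Replicate single-site trajectories under a size history.

    Each replicate is a new mutation starting at 1/2N(t0); per generation
    q <- Binomial(2N(t+1), q + s*p*q*(q-1/2)) / 2N(t+1).  Origins are
    drawn proportional to the mutational influx 2N(t)u
    (``uniform-influx``) or all placed at t = 0 (``fixed-time``).
    Trajectories that are still segregating when the schedule ends are
    recorded at the present; under ``fixed-time`` with a constant history
    the schedule is extended until every replicate is absorbed (capped at
    ``max_gens``), which makes it the right tool for equilibrium
    per-mutation statistics.
    """
    _check_s(s)
    if origin_policy not in ("uniform-influx", "fixed-time"):
        raise ValueError(f"unknown origin_policy {origin_policy!r}")
    rng = np.random.default_rng(seed)
    sizes = demography.sizes()
    T = len(sizes)

    if origin_policy == "fixed-time":
        origin = np.zeros(n_reps, dtype=np.int64)
    else:
        wts = sizes.astype(float)
        origin = rng.choice(T, size=n_reps, p=wts / wts.sum()).astype(np.int64)

    q = 1.0 / (2 * sizes[origin])
    sum_pq = np.zeros(n_reps)
    extend = origin_policy == "fixed-time"
    cap = max_gens if max_gens is not None else 200 * int(sizes.max())

    alive = np.arange(n_reps)
    t = 0
    while alive.size and t < cap:
        if t >= T and not extend:
            break
        N_next = int(sizes[t + 1]) if t + 1 < T else int(sizes[-1])
        born = origin[alive] <= t
        idx = alive[born]
        if idx.size:
            qa = q[idx]
            sum_pq[idx] += qa * (1 - qa)
            p_next = np.clip(qa + s * qa * (1 - qa) * (qa - 0.5), 0.0, 1.0)
            q[idx] = rng.binomial(2 * N_next, p_next) / (2 * N_next)
        absorbed = (q[alive] <= 0) | (q[alive] >= 1)
        # only count replicates already born as absorbable
        done = absorbed & born
        alive = alive[~done]
        t += 1
        if t >= T and not extend:
            break

    n_traits = params.n if params is not None else np.inf
    eps = sample_eps(n_traits, n_reps, rng, mode=eps_mode)
    return TrajectoryEnsemble(
        s=s, origin=origin, final_q=q, sum_pq=sum_pq, eps=eps,
        seed=seed if isinstance(seed, int) else None,
        metadata={
            "origin_policy": origin_policy,
            "n_reps": n_reps,
            "total_gens": T,
            "eps_mode": eps_mode,
            "extended_to_absorption": bool(extend),
        },
    )


def variance_by_s_under_demography(s_grid, demography: Demography,
                                   params: ModelParams,
                                   n_events: int = 5000, seed=None,
                                   thresholds=None,
                                   eps_mode: str = "pleiotropic-limit") -> pd.DataFrame:
    """Present-day variance statistics per selection coefficient under a
    size history, with equilibrium standing variation at the start.

    For each s, mutation events are sampled from the model's stationary
    influx: standing variants at t = 0 (count expected 2*N0*u*Tbar per
    site, frequencies from the normalized sojourn density at N0) plus new
    mutations arising at rate 2*N(t)*u.  Events are simulated to the
    present and their contributions 2*a1**2*p*q are aggregated.

    Returns one row per s with the expected per-site variance in units of
    4u*w**2/n (the equilibrium per-site total for a strongly selected
    site), the mean contribution per segregating site (units w**2/n), and
    cumulative variance above each requested threshold (thresholds in
    units of w**2/n).
    """
    rng = np.random.default_rng(seed)
    sizes = demography.sizes()
    N0 = int(sizes[0])
    T = len(sizes)
    unit_site = 4 * params.u * params.w**2 / params.n   # per-site variance unit
    rows = []
    thresholds = np.asarray(thresholds, dtype=float) if thresholds is not None else None

    for s in np.atleast_1d(np.asarray(s_grid, dtype=float)):
        _check_s(s)
        S0 = 2 * N0 * s
        dens = sojourn_density(S0, N0)
        Tbar = dens.total_time()
        w_standing = 2 * N0 * Tbar          # expected events per site / u
        w_influx = 2.0 * sizes.sum()
        W = w_standing + w_influx

        n_standing = int(round(n_events * w_standing / W))
        n_new = n_events - n_standing

        # standing variants: snapshot frequencies from the sojourn density
        cdf = np.concatenate([[0.0], np.cumsum(
            (dens.t[1:] + dens.t[:-1]) / 2 * np.diff(dens.q))])
        cdf /= cdf[-1]
        q_stand = np.interp(rng.random(n_standing), cdf, dens.q)
        # new mutations: origins proportional to 2N(t)
        wts = sizes.astype(float)
        origin_new = rng.choice(T, size=n_new, p=wts / wts.sum()).astype(np.int64)

        q = np.concatenate([q_stand, 1.0 / (2 * sizes[origin_new])])
        origin = np.concatenate([np.zeros(n_standing, dtype=np.int64), origin_new])

        # advance to the present
        alive = np.arange(n_events)
        for t in range(T):
            N_next = int(sizes[t + 1]) if t + 1 < T else int(sizes[-1])
            born = origin[alive] <= t
            idx = alive[born]
            if idx.size:
                qa = q[idx]
                p_next = np.clip(qa + s * qa * (1 - qa) * (qa - 0.5), 0.0, 1.0)
                q[idx] = rng.binomial(2 * N_next, p_next) / (2 * N_next)
            absorbed = ((q[alive] <= 0) | (q[alive] >= 1)) & born
            alive = alive[~absorbed]

        eps = sample_eps(params.n, n_events, rng, mode=eps_mode)
        w2n = params.w**2 / params.n
        v = 2 * w2n * s * eps * q * (1 - q)  # raw units; 0 if absorbed
        seg = (q > 0) & (q < 1)

        # eps is independent of the trajectory with E(eps) = 1, so the
        # unthresholded means are computed with eps marginalized out
        # (exact, and much lower Monte Carlo variance than sampling the
        # heavy-tailed chi-square multiplier)
        v_marg = 2 * w2n * s * q * (1 - q)
        per_site_var = params.u * W * v_marg.mean() if n_events else 0.0
        row = {
            "s": s,
            "S_start": S0,
            "n_events": n_events,
            "n_segregating": int(seg.sum()),
            "per_site_variance": per_site_var / unit_site,
            "per_seg_site_mean": (v_marg[seg].mean() / w2n
                                  if seg.any() else 0.0),
        }
        if thresholds is not None:
            vu = v / w2n
            for thr in thresholds:
                row[f"cumvar_above_{thr:g}"] = (
                    params.u * W * np.where(vu > thr, v, 0.0).mean() / unit_site)
        rows.append(row)

    df = pd.DataFrame(rows)
    df.attrs["units"] = {
        "per_site_variance": "4*u*w^2/n",
        "per_seg_site_mean": "w^2/n",
        "thresholds": "w^2/n",
    }
    df.attrs["seed"] = seed
    df.attrs["standing_init"] = "equilibrium sojourn density of first epoch"
    return df


def simulate_multilocus(params: ModelParams, generations: int, seed=None,
                        mutation_size: float | None = None,
                        burn_in: int | None = None) -> dict:
    """Individual-based simulation of the full model, for validation.

    Diploid Wright-Fisher with viability selection exp(-r^2/2w^2) on the
    n-dimensional phenotype, Poisson(U) mutations per gamete at L finite
    sites with fixed per-site effect vectors (size ``mutation_size``,
    isotropic direction), free recombination.  Tracks the trait mean,
    per-axis variance, a normality diagnostic, and accumulates the
    regression of per-site frequency change on p*q*(q-1/2), whose slope
    estimates a^2/w^2.

    Scale guard: intended for modest L (<= 1e4) and N (<= 2000).
    """
    if params.L > 10_000 or params.N > 2000:
        raise ValueError("multilocus mode is for validation scales "
                         "(L <= 1e4, N <= 2000)")
    rng = np.random.default_rng(seed)
    N, L = params.N, params.L
    n_tr = int(round(params.n))
    if mutation_size is None:
        mutation_size = 0.2 * params.w * np.sqrt(1.0 / (2 * N))  # S ~ 0.04... small
    a = float(mutation_size)
    if burn_in is None:
        burn_in = generations // 3

    # fixed per-site effect vectors of size a, isotropic directions
    dirs = rng.normal(size=(L, n_tr))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    A = a * dirs

    X = np.zeros((N, L), dtype=np.int8)      # derived-allele counts
    s_theory = a**2 / params.w**2

    Sxy = 0.0
    Sxx = 0.0
    mean_traj = []
    for t in range(generations):
        Z = X @ A                              # phenotypes
        fit = np.exp(-np.einsum("ij,ij->i", Z, Z) / (2 * params.w**2))
        sigma2 = Z.var(axis=0).mean()
        if sigma2 > params.w**2:
            raise RuntimeError(
                f"runaway variance at generation {t}: sigma^2 = {sigma2:.3g} "
                f"> w^2 = {params.w**2:.3g}")
        prob = fit / fit.sum()
        q_before = X.mean(axis=0) / 2.0

        parents = rng.choice(N, size=(N, 2), p=prob)
        g1 = rng.random((N, L)) < X[parents[:, 0]] / 2.0
        g2 = rng.random((N, L)) < X[parents[:, 1]] / 2.0

        if t >= burn_in:
            # frequency change from selection + drift only (pre-mutation),
            # the quantity the marginal underdominant drift describes
            q_after = (g1.sum(axis=0) + g2.sum(axis=0)) / (2.0 * N)
            x = q_before * (1 - q_before) * (q_before - 0.5)
            seg = (q_before > 0) & (q_before < 1)
            Sxy += float(np.dot(x[seg], (q_after - q_before)[seg]))
            Sxx += float(np.dot(x[seg], x[seg]))
            mean_traj.append(Z.mean(axis=0))

        # mutation: Poisson(U) per gamete at uniform sites (recurrent
        # finite-sites stand-in for infinite sites at theta << 1)
        for gam in (g1, g2):
            n_mut = rng.poisson(params.U, N)
            hit_rows = np.repeat(np.arange(N), n_mut)
            if hit_rows.size:
                hit_cols = rng.integers(0, L, hit_rows.size)
                gam[hit_rows, hit_cols] = True
        X = g1.astype(np.int8) + g2.astype(np.int8)

    Z = X @ A
    mean_traj = np.asarray(mean_traj)
    sigma2_axes = Z.var(axis=0)
    focal = Z[:, 0]
    norm_p = float(stats.normaltest(focal).pvalue) if np.std(focal) > 0 else np.nan
    return {
        "trait_means": Z.mean(axis=0),
        "mean_abs_trait_mean": float(np.abs(mean_traj).mean()) if mean_traj.size else np.nan,
        "sigma2": float(sigma2_axes.mean()),
        "sigma2_axes": sigma2_axes,
        "normality_p": norm_p,
        "drift_slope": Sxy / Sxx if Sxx > 0 else np.nan,
        "drift_slope_theory": s_theory,
        "mutation_size": a,
        "seed": seed,
        "generations": generations,
        "burn_in": burn_in,
    }
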
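"""GWAS-facing inference: detection thresholds, the one-parameter fit of
v_s to the variances of genome-wide-significant loci, goodness of fit,
mutational target size, and discovery projections.

The detection model is a step function: a study of size m on a trait
with phenotypic variance V_P detects every locus whose contribution to
additive variance exceeds v* = c*V_P/m and none below.  The calibration
constant c defaults to the chi-square(1 df) noncentrality giving 50%
power at genome-wide significance (alpha = 5e-8), c ~ 29.7.

Among detected loci (all under intermediate/strong selection once v* is
of order v_s), the model predicts the distribution of per-locus
variances v through a single parameter v_s.  In the pleiotropic
strong-selection limit the *number* density of segregating sites is

    f(v)  ∝  exp(-2*sqrt(v/v_s)) / v        on v >= v*,

whose survival function is E1(2*sqrt(v/v_s)) / E1(2*sqrt(v*/v_s)) (E1
the exponential integral) and whose variance-weighted survival is
exactly the architecture curve G(v) = (1+2*sqrt(v/v_s))
* exp(-2*sqrt(v/v_s)).  That consistency (checked in the tests against
the numeric oracle) is what ties the fit back to the diffusion theory.
``family="variance"`` instead treats the data as variance-weighted draws
with density ∝ exp(-2*sqrt(v/v_s)), the form matching G directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import exp1

from .model import ModelParams
from .architecture import sites_above_strong_limit, G_closed
from .pleiotropy import _MODES  # ("pleiotropic-limit", "exact-n")

__all__ = [
    "GWASTable",
    "FitResult",
    "power_constant",
    "detection_threshold",
    "fit_vs",
    "sample_from_family",
    "ks_goodness_of_fit",
    "estimate_target_size",
    "project_discovery",
]


@dataclass
class GWASTable:
    """Per-locus summary records plus trait metadata.

    ``frame`` has columns snp, freq, beta (per-allele effect, trait
    units) and var_explained (2*beta**2*p*q, trait-variance units); V_P
    and h2 are the phenotypic variance and heritability in the same
    units; m is the study size.
    """

    frame: pd.DataFrame
    V_P: float | None = None
    h2: float | None = None
    m: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        if "var_explained" not in df.columns:
            if not {"freq", "beta"}.issubset(df.columns):
                raise ValueError("need var_explained or (freq, beta) columns")
            df = df.assign(
                var_explained=2 * df["beta"] ** 2 * df["freq"] * (1 - df["freq"]))
        bad = ~np.isfinite(df["var_explained"]) | (df["var_explained"] < 0)
        if "freq" in df.columns:
            bad |= ~((df["freq"] > 0) & (df["freq"] < 1))
        self.n_dropped = int(bad.sum())
        self.frame = df.loc[~bad].reset_index(drop=True)

    @property
    def v(self) -> np.ndarray:
        """Per-locus variance explained, trait-variance units."""
        return self.frame["var_explained"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class FitResult:
    """Outcome of the one-parameter (v_s) architecture fit."""

    vs: float
    vstar: float
    n_loci: int
    mode: str = "pleiotropic-limit"
    family: str = "sites"
    n_traits: float | None = None
    loglik: float = np.nan
    L: float | None = None
    detectable_fraction: float | None = None
    ks_D: float | None = None
    ks_p: float | None = None
    ci: dict = field(default_factory=dict)
    bootstrap_samples: pd.DataFrame | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "vs": self.vs, "vstar": self.vstar, "n_loci": self.n_loci,
            "mode": self.mode, "family": self.family,
            "n_traits": self.n_traits, "loglik": self.loglik,
            "L": self.L, "detectable_fraction": self.detectable_fraction,
            "ks_D": self.ks_D, "ks_p": self.ks_p, "seed": self.seed,
            "ci": {k: list(map(float, bounds)) for k, bounds in self.ci.items()},
        }
        return out


def power_constant(alpha: float = 5e-8, power: float = 0.5) -> float:
    """Noncentrality c of the 1-df association chi-square at which a locus
    is detected with probability `power` at significance `alpha`.  The
    expected test statistic of a locus explaining fraction v/V_P of the
    phenotypic variance in a study of size m is ~ m*v/V_P, so detection
    at 50% power corresponds to v >= c*V_P/m."""
    crit = stats.chi2.ppf(1 - alpha, df=1)
    return float(optimize.brentq(
        lambda ncp: stats.ncx2.sf(crit, 1, ncp) - power, 1e-6, 10 * crit))


def detection_threshold(m: float, V_P: float, calibration: float | None = None,
                        alpha: float = 5e-8, power: float = 0.5) -> float:
    """Step-function detection threshold v* = c*V_P/m."""
    if m <= 0 or V_P <= 0:
        raise ValueError("m and V_P must be positive")
    c = power_constant(alpha, power) if calibration is None else calibration
    if c <= 0:
        raise ValueError("calibration constant must be positive")
    return c * V_P / m


# ---------------------------------------------------------------------------
# Truncated strong-selection family
# ---------------------------------------------------------------------------

def _family_logpdf(v, vs, vstar, mode, family, n_traits=None):
    """Log density of per-locus variance on v >= vstar (unnormalized in v,
    normalized over the truncated support)."""
    v = np.asarray(v, dtype=float)
    if family == "sites":
        if vstar <= 0:
            raise ValueError(
                "the site-count family needs v* > 0 (sites pile up "
                "without bound at small v)")
        if mode == "pleiotropic-limit":
            logZ = np.log(2 * exp1(2 * np.sqrt(vstar / vs)))
            return -2 * np.sqrt(v / vs) - np.log(v) - logZ
        if n_traits == 1:
            logZ = np.log(exp1(2 * vstar / vs))
            return -2 * v / vs - np.log(v) - logZ
        # general n: mixture over eps = n*Beta(1/2,(n-1)/2)
        from .architecture import _eps_quadrature, _trapz_weights
        eps, wts, x = _eps_quadrature(n_traits, "exact-n")
        dx = _trapz_weights(x)
        mix = (wts * dx)[None, :]
        dens = np.sum(mix * np.exp(-2 * v[:, None] / (vs * eps[None, :])), axis=1)
        Z = np.sum((wts * dx) * exp1(2 * vstar / (vs * eps)))
        return np.log(dens) - np.log(v) - np.log(Z)
    if family == "variance":
        if mode == "pleiotropic-limit":
            # int_{v*}^inf e^{-2 sqrt(v/vs)} dv = vs/2 * (1+2u*) e^{-2u*}
            ustar = np.sqrt(vstar / vs)
            logZ = np.log(vs / 2) + np.log1p(2 * ustar) - 2 * ustar
            return -2 * np.sqrt(v / vs) - logZ
        if n_traits == 1:
            return -2 * (v - vstar) / vs - np.log(vs / 2)
        raise ValueError("variance family implements the limit and n=1 forms")
    raise ValueError(f"unknown family {family!r}")


def _family_cdf(v, vs, vstar, mode, family, n_traits=None):
    v = np.asarray(v, dtype=float)
    v = np.maximum(v, vstar)
    if family == "sites":
        if mode == "pleiotropic-limit":
            sf = exp1(2 * np.sqrt(v / vs)) / exp1(2 * np.sqrt(vstar / vs))
        elif n_traits == 1:
            sf = exp1(2 * v / vs) / exp1(2 * vstar / vs)
        else:
            from .architecture import _eps_quadrature, _trapz_weights
            eps, wts, x = _eps_quadrature(n_traits, "exact-n")
            dx = _trapz_weights(x)
            num = np.sum((wts * dx)[None, :] * exp1(2 * v[:, None] / (vs * eps[None, :])), axis=1)
            den = np.sum((wts * dx) * exp1(2 * vstar / (vs * eps)))
            sf = num / den
    else:
        if mode == "pleiotropic-limit":
            u, ustar = np.sqrt(v / vs), np.sqrt(vstar / vs)
            sf = (1 + 2 * u) * np.exp(-2 * u) / ((1 + 2 * ustar) * np.exp(-2 * ustar))
        elif n_traits == 1:
            sf = np.exp(-2 * (v - vstar) / vs)
        else:
            raise ValueError("variance family implements the limit and n=1 forms")
    return 1.0 - sf


def sample_from_family(size, vs, vstar, rng, mode="pleiotropic-limit",
                       family="sites", n_traits=None) -> np.ndarray:
    """Draw per-locus variances from the truncated family (exact samplers)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n1 = mode == "exact-n" and n_traits == 1
    if family == "sites" and not n1 and mode == "pleiotropic-limit":
        # u = sqrt(v/vs) has density ∝ exp(-2u)/u on u >= u*:
        # rejection from the shifted exponential with accept prob u*/u
        ustar = np.sqrt(vstar / vs)
        if ustar <= 0:
            raise ValueError("site-count family needs v* > 0")
        out = np.empty(0)
        while out.size < size:
            k = int((size - out.size) * 3 + 16)
            u = ustar + rng.exponential(0.5, k)
            out = np.concatenate([out, u[rng.random(k) < ustar / u]])
        return vs * out[:size] ** 2
    if family == "sites" and n1:
        # density ∝ exp(-2v/vs)/v on v >= v*: same rejection trick in v
        out = np.empty(0)
        while out.size < size:
            k = int((size - out.size) * 3 + 16)
            v = vstar + rng.exponential(vs / 2, k)
            out = np.concatenate([out, v[rng.random(k) < vstar / v]])
        return out[:size]
    if family == "variance" and not n1 and mode == "pleiotropic-limit":
        # u density ∝ u*exp(-2u) on u >= u*: exact mixture of a shifted
        # exponential and a shifted Gamma(2) (u*e^{-2u} = (u* + (u-u*))e^{-2u})
        ustar = np.sqrt(vstar / vs)
        p_exp = ustar / (ustar + 0.5)
        pick = rng.random(size) < p_exp
        u = np.where(pick,
                     ustar + rng.exponential(0.5, size),
                     ustar + rng.gamma(2.0, 0.5, size))
        return vs * u**2
    if family == "variance" and n1:
        return vstar + rng.exponential(vs / 2, size)
    # generic fallback: numeric inverse CDF
    grid = vstar * np.geomspace(1, 1e4, 4000)
    cdf = _family_cdf(grid, vs, vstar, mode, family, n_traits)
    return np.interp(rng.random(size), cdf, grid)


def fit_vs(table: GWASTable | np.ndarray, vstar: float,
           mode: str = "pleiotropic-limit", family: str = "sites",
           n_traits: float | None = None,
           bootstrap: int = 0, seed=None) -> FitResult:
    """Maximum-likelihood v_s from the variances of detected loci.

    ``table`` may be a GWASTable or a plain array of per-locus variances;
    loci below v* are excluded (error if none remain).  ``mode``
    "pleiotropic-limit" is the default (the fits to real traits favor
    it); "exact-n" with ``n_traits`` fits the finite-n family, and
    ``n_traits=None`` there profiles n over a grid.  Optional parametric
    bootstrap gives percentile CIs.
    """
    v_all = table.v if isinstance(table, GWASTable) else np.asarray(table, float)
    v = v_all[v_all >= vstar]
    if v.size == 0:
        raise ValueError("no loci at or above the detection threshold v*")
    if v.size < 20:
        warnings.warn(f"only {v.size} loci above v*: the fit will be weak",
                      stacklevel=2)
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")

    if mode == "exact-n" and n_traits is None:
        # profile n over a grid, refit vs at each
        grid = [1, 2, 3, 5, 10, 20, 50, 100]
        fits = [fit_vs(v, vstar, mode="exact-n", n_traits=k, family=family)
                for k in grid]
        best = int(np.argmax([f.loglik for f in fits]))
        limit_fit = fit_vs(v, vstar, mode="pleiotropic-limit", family=family,
                           bootstrap=bootstrap, seed=seed)
        if limit_fit.loglik >= fits[best].loglik - 1e-9:
            return limit_fit
        res = fits[best]
        if bootstrap:
            res = fit_vs(v, vstar, mode="exact-n", n_traits=grid[best],
                         family=family, bootstrap=bootstrap, seed=seed)
        return res

    center = np.log(max(np.mean(v), vstar))

    def nll(log_vs):
        return -float(np.sum(_family_logpdf(
            v, np.exp(log_vs), vstar, mode, family, n_traits)))

    opt = optimize.minimize_scalar(nll, bounds=(center - 10, center + 10),
                                   method="bounded", options={"xatol": 1e-10})
    if not opt.success:
        raise RuntimeError(f"v_s likelihood optimization failed: {opt}")
    vs_hat = float(np.exp(opt.x))

    result = FitResult(vs=vs_hat, vstar=float(vstar), n_loci=int(v.size),
                       mode=mode, family=family, n_traits=n_traits,
                       loglik=-float(opt.fun),
                       seed=seed if isinstance(seed, int) else None)
    if bootstrap:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(bootstrap):
            vb = sample_from_family(v.size, vs_hat, vstar, rng, mode=mode,
                                    family=family, n_traits=n_traits)
            fb = fit_vs(vb, vstar, mode=mode, family=family, n_traits=n_traits)
            reps.append(fb.vs)
        reps = np.asarray(reps)
        result.bootstrap_samples = pd.DataFrame({"vs": reps})
        result.ci["vs"] = _log_basic_ci(vs_hat, reps)
    return result


def _log_basic_ci(estimate: float, boot: np.ndarray,
                  level: float = 95.0) -> tuple[float, float]:
    """Basic (reverse-percentile) bootstrap interval on the log scale.

    v_s and L are scale parameters, so log(hat/true) is close to pivotal;
    the basic interval on logs is better calibrated than the raw
    percentile interval for their skewed sampling distributions.
    """
    d = np.log(np.asarray(boot, dtype=float) / estimate)
    a = (100.0 - level) / 2.0
    lo = estimate * np.exp(-np.percentile(d, 100.0 - a))
    hi = estimate * np.exp(-np.percentile(d, a))
    return (float(lo), float(hi))


def ks_goodness_of_fit(table: GWASTable | np.ndarray, fit: FitResult,
                       method: str = "classic", n_boot: int = 199,
                       seed=None) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of the detected-loci variances against the
    fitted truncated family.

    ``classic`` uses the asymptotic KS distribution (comparable to
    published fits but conservative, since v_s was estimated from the
    same data); ``bootstrap`` refits each parametric resample, giving a
    calibrated p-value.
    """
    v_all = table.v if isinstance(table, GWASTable) else np.asarray(table, float)
    v = v_all[v_all >= fit.vstar]
    cdf = lambda x: _family_cdf(x, fit.vs, fit.vstar, fit.mode, fit.family,
                                fit.n_traits)
    D, p = stats.kstest(v, cdf)
    if method == "classic":
        return float(D), float(p)
    if method != "bootstrap":
        raise ValueError("method must be 'classic' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        vb = sample_from_family(v.size, fit.vs, fit.vstar, rng, mode=fit.mode,
                                family=fit.family, n_traits=fit.n_traits)
        fb = fit_vs(vb, fit.vstar, mode=fit.mode, family=fit.family,
                    n_traits=fit.n_traits)
        Db, _ = stats.kstest(vb, lambda x: _family_cdf(
            x, fb.vs, fit.vstar, fit.mode, fit.family, fit.n_traits))
        exceed += Db >= D
    return float(D), (exceed + 1) / (n_boot + 1)


def estimate_target_size(table: GWASTable | np.ndarray, fit: FitResult,
                         params: ModelParams,
                         bootstrap: int = 0, seed=None) -> FitResult:
    """Mutational target size and detectable variance fraction.

    The expected number of detected loci is L * 2Nu * C(v*/v_s), with C
    the strong-limit per-mutation sojourn count above threshold, so the
    observed count gives L.  The variance arising from the detectable
    (intermediate/strong) selection range is L * 2Nu * v_s; divided by
    the heritable variance h2*V_P it is the fraction of heritability that
    GWAS can ever reach within this selection range.  Results are
    attached to (a copy of) ``fit`` and returned.
    """
    v_all = table.v if isinstance(table, GWASTable) else np.asarray(table, float)
    count = int(np.sum(v_all >= fit.vstar))
    if count == 0:
        raise ValueError("no observed loci above v*: target size undefined")
    theta_half = 2 * params.N * params.u
    eff_n = fit.n_traits if fit.mode == "exact-n" else None
    eff_mode = "exact-n" if fit.mode == "exact-n" else "pleiotropic-limit"
    C = float(sites_above_strong_limit(fit.vstar / fit.vs, n=eff_n, mode=eff_mode))
    fit.L = count / (theta_half * C)

    V_P = table.V_P if isinstance(table, GWASTable) else None
    h2 = table.h2 if isinstance(table, GWASTable) else None
    if V_P is not None and h2 is not None:
        fit.detectable_fraction = float(
            np.clip(fit.L * theta_half * fit.vs / (h2 * V_P), 0.0, 1.0))

    if bootstrap:
        rng = np.random.default_rng(seed)
        Ls, fracs = [], []
        for _ in range(bootstrap):
            nb = rng.poisson(count)
            if nb == 0:
                continue
            vb = sample_from_family(nb, fit.vs, fit.vstar, rng, mode=fit.mode,
                                    family=fit.family, n_traits=fit.n_traits)
            fb = fit_vs(vb, fit.vstar, mode=fit.mode, family=fit.family,
                        n_traits=fit.n_traits)
            Cb = float(sites_above_strong_limit(fit.vstar / fb.vs, n=eff_n,
                                                mode=eff_mode))
            Lb = nb / (theta_half * Cb)
            Ls.append(Lb)
            if V_P is not None and h2 is not None:
                fracs.append(np.clip(Lb * theta_half * fb.vs / (h2 * V_P), 0, 1))
        fit.ci["L"] = _log_basic_ci(fit.L, np.asarray(Ls))
        if fracs:
            fit.ci["detectable_fraction"] = _log_basic_ci(
                fit.detectable_fraction, np.asarray(fracs))
    return fit


def project_discovery(fit: FitResult, m_grid, params: ModelParams,
                      V_P: float | None = None,
                      calibration: float | None = None) -> pd.DataFrame:
    """Heritability explained and number of hits as functions of study size.

    For each m: v*(m) = c*V_P/m; the explained fraction of heritability
    is detectable_fraction * G(v*(m)/v_s) (G the strong-limit variance
    survival, which tends to 1 as v* -> 0 so the curve saturates at the
    detectable fraction); the hit count is L * 2Nu * C(v*(m)/v_s).
    """
    if fit.L is None:
        raise ValueError("run estimate_target_size first (needs L)")
    if V_P is None:
        V_P = 1.0
    m_grid = np.asarray(m_grid, dtype=float)
    frac = fit.detectable_fraction if fit.detectable_fraction is not None else 1.0
    theta_half = 2 * params.N * params.u
    c = power_constant() if calibration is None else calibration
    rows = []
    for m in m_grid:
        vstar_m = c * V_P / m
        x = vstar_m / fit.vs
        G = float(G_closed(x, regime="strong-limit"))
        hits = fit.L * theta_half * float(sites_above_strong_limit(x))
        rows.append({"m": m, "vstar": vstar_m,
                     "explained_fraction": frac * G, "n_hits": hits})
    df = pd.DataFrame(rows)
    if fit.bootstrap_samples is not None and "vs" in fit.bootstrap_samples:
        lo_vs, hi_vs = np.percentile(fit.bootstrap_samples["vs"], [2.5, 97.5])
        df["explained_lo"] = [frac * float(G_closed(r.vstar / hi_vs, regime="strong-limit"))
                              for r in df.itertuples()]
        df["explained_hi"] = [frac * float(G_closed(r.vstar / lo_vs, regime="strong-limit"))
                              for r in df.itertuples()]
    return df
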
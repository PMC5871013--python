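"""Synthetic architecture and GWAS tables with the model's exact
statistical structure.

Frequencies are drawn from the normalized sojourn density (a snapshot of
segregating sites at equilibrium), effects from the selection-effect
geometry, so the joint (q, a1) law is the product the theory predicts.
Thresholding by the step-function power model then yields GWAS-like hit
tables, which makes every inference operation testable without any
external download.  Demography-aware tables come from
:mod:`quantgen_arch.wrightfisher` instead.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .model import ModelParams
from .architecture import sojourn_density
from .pleiotropy import sample_eps
from .inference import GWASTable, detection_threshold

__all__ = ["SynthSpec", "generate_architecture", "generate_gwas_table"]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic architecture sample.

    ``S_dist`` is a point mass (scalar) or a sequence of (S, weight)
    pairs — the model leaves the distribution of selection coefficients
    free, so it is an explicit generator knob.  ``n_sites`` segregating
    sites are drawn; ``m`` and ``V_P`` set the detection threshold when
    a GWAS table is requested.
    """

    params: ModelParams
    S_dist: object = 100.0
    n_sites: int = 10_000
    m: float = 1e6
    V_P: float = 1.0
    h2: float | None = 0.5
    mode: str = "pleiotropic-limit"

    def s_weights(self) -> tuple[np.ndarray, np.ndarray]:
        if np.isscalar(self.S_dist):
            return np.array([float(self.S_dist)]), np.array([1.0])
        arr = np.asarray(self.S_dist, dtype=float)
        S, w = arr[:, 0], arr[:, 1]
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("S_dist weights must be nonnegative and sum to 1")
        return S, w

    def spec_hash(self) -> str:
        payload = {
            "params": self.params.to_dict(),
            "S_dist": np.asarray(self.S_dist, dtype=float).tolist()
            if not np.isscalar(self.S_dist) else float(self.S_dist),
            "n_sites": self.n_sites, "m": self.m, "V_P": self.V_P,
            "h2": self.h2, "mode": self.mode,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _sample_freqs(S: float, N: int, size: int, rng: np.random.Generator) -> np.ndarray:
    dens = sojourn_density(S, N)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(dens.t, dens.q)])
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, dens.q)


def generate_architecture(spec: SynthSpec, seed=None) -> pd.DataFrame:
    """Per-site table (S, q, a1, v): the equilibrium joint law.

    S is drawn from the spec's distribution, q from the normalized
    sojourn density t(q; S), a1 from the effect geometry given S, and
    v = 2*a1**2*p*q (raw trait-variance units).
    """
    rng = np.random.default_rng(seed)
    Svals, wts = spec.s_weights()
    N, w2n = spec.params.N, spec.params.w**2 / spec.params.n
    which = rng.choice(len(Svals), size=spec.n_sites, p=wts)
    S_site = Svals[which]
    q = np.empty(spec.n_sites)
    for i, S in enumerate(Svals):
        sel = which == i
        if sel.any():
            q[sel] = _sample_freqs(S, N, int(sel.sum()), rng)
    eps = sample_eps(spec.params.n, spec.n_sites, rng, mode=spec.mode)
    s_site = S_site / (2 * N)
    a1 = rng.choice([-1.0, 1.0], spec.n_sites) * np.sqrt(w2n * s_site * eps)
    v = 2 * a1**2 * q * (1 - q)
    df = pd.DataFrame({"S": S_site, "q": q, "a1": a1, "v": v})
    df.attrs["seed"] = seed
    df.attrs["spec_hash"] = spec.spec_hash()
    return df


def generate_gwas_table(spec: SynthSpec, seed=None, noise: bool = False,
                        calibration: float | None = None) -> GWASTable:
    """GWAS-like hit table: architecture sites thresholded at v*(m).

    Emits (snp, freq, beta) with 2*beta**2*p*q = v exactly; with
    ``noise`` the reported beta gets the sampling error of a study of
    size m, se = sqrt(V_P / (2*m*p*q)).
    """
    rng = np.random.default_rng(seed)
    arch = generate_architecture(spec, seed=rng.integers(2**31))
    vstar = detection_threshold(spec.m, spec.V_P, calibration=calibration)
    hits = arch[arch["v"] >= vstar].reset_index(drop=True)
    if len(hits) == 0:
        warnings.warn(
            f"no sites reach the detection threshold v* = {vstar:.3g} at "
            f"study size m = {spec.m:.3g}", stacklevel=2)
    beta = hits["a1"].to_numpy().copy()
    if noise and len(hits):
        se = np.sqrt(spec.V_P / (2 * spec.m * hits["q"] * (1 - hits["q"])))
        beta = beta + rng.normal(0, se)
    frame = pd.DataFrame({
        "snp": [f"snp{i}" for i in range(len(hits))],
        "freq": hits["q"].to_numpy(),
        "beta": beta,
    })
    table = GWASTable(frame=frame, V_P=spec.V_P, h2=spec.h2, m=spec.m)
    table.metadata.update(seed=seed, spec_hash=spec.spec_hash(), vstar=vstar,
                          noise=noise)
    return table
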
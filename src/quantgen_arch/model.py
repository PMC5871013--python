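"""Model parameters and unit conventions.

The model: a focal quantitative trait is one axis of an ``n``-dimensional
trait space under Gaussian stabilizing selection of strength ``w`` (trait
units per unit fitness).  A diploid Wright-Fisher population of size ``N``
accumulates mutations at ``L`` target sites at per-site rate ``u``.  An
allele with effect vector of Euclidean length ``a`` experiences
underdominant selection with coefficient ``s = a**2 / w**2`` (scaled:
``S = 2*N*s``), and a strongly selected site contributes on average

    v_s = 2 * w**2 / (n * N)

to the additive genetic variance of the focal trait.  ``v_s`` is the unit
of variance used throughout the package.  ``n`` may be any real >= 1 and is
read as the *effective* number of traits, which absorbs anisotropic
mutation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "EffectVector",
    "SelectionCoefficient",
    "RegimeWarning",
    "selection_from_effect",
    "vs_unit",
    "load_params",
]


class RegimeWarning(UserWarning):
    """A parameter leaves the regime in which the model's approximations
    are accurate.  The theory degrades gracefully, so this is a warning,
    never an error."""


@dataclass(frozen=True)
class ModelParams:
    """Population-genetic and trait-space parameters.

    Parameters
    ----------
    n : float
        (Effective) number of traits, real-valued, >= 1.
    w : float
        Strength of stabilizing selection, trait units per unit fitness.
        Larger ``w`` means weaker selection.
    N : int
        Diploid population size.
    u : float
        Per-site, per-gamete mutation rate.
    L : int
        Mutational target size, in sites.
    """

    n: float
    w: float
    N: int
    u: float
    L: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and self.n >= 1):
            raise ValueError(f"n must be a real >= 1, got {self.n}")
        if not (np.isfinite(self.w) and self.w > 0):
            raise ValueError(f"w must be positive, got {self.w}")
        if not (self.N == int(self.N) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        if not (np.isfinite(self.u) and self.u > 0):
            raise ValueError(f"u must be positive, got {self.u}")
        if not (self.L == int(self.L) and self.L >= 1):
            raise ValueError(f"L must be a positive integer, got {self.L}")
        if self.theta > 0.1:
            warnings.warn(
                f"theta = 4Nu = {self.theta:.3g} > 0.1: the infinite-sites "
                "(biallelic) approximation is suspect",
                RegimeWarning,
                stacklevel=2,
            )
        if not (1.0 / (2 * self.N) < self.U < 1.0):
            warnings.warn(
                f"U = L*u = {self.U:.3g} outside (1/2N, 1): the model "
                "assumes 1 >> U >> 1/2N",
                RegimeWarning,
                stacklevel=2,
            )

    @property
    def U(self) -> float:
        """Genome-wide (per-gamete) mutation rate toward the trait, L*u."""
        return self.L * self.u

    @property
    def theta(self) -> float:
        """Per-site population mutation rate, 4*N*u."""
        return 4 * self.N * self.u

    @property
    def vs(self) -> float:
        """Expected variance contributed by a strongly selected site,
        2*w**2/(n*N).  The unit of variance throughout."""
        return 2 * self.w**2 / (self.n * self.N)

    def to_dict(self) -> dict:
        return {"n": self.n, "w": self.w, "N": self.N, "u": self.u, "L": self.L}


def vs_unit(params: ModelParams) -> float:
    """The per-site variance unit v_s = 2*w**2/(n*N)."""
    return params.vs


@dataclass(frozen=True)
class EffectVector:
    """Phenotypic effect of an allele: a vector in n-dimensional trait space."""

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple(float(c) for c in self.components)
        if not all(math.isfinite(c) for c in comps):
            raise ValueError("effect components must be finite")
        object.__setattr__(self, "components", comps)

    @property
    def size(self) -> float:
        """Euclidean norm ``a`` of the effect vector."""
        return float(np.linalg.norm(self.components))

    @property
    def a1(self) -> float:
        """Effect on the focal (first) trait."""
        return self.components[0]


@dataclass(frozen=True)
class SelectionCoefficient:
    """Unscaled (s) and scaled (S = 2Ns) selection coefficient of an allele."""

    s: float
    S: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s) and self.s >= 0):
            raise ValueError(f"s must be >= 0, got {self.s}")
        if self.s > 0.1:
            warnings.warn(
                f"s = {self.s:.3g} > 0.1: the weak-selection (s << 1) "
                "approximation is suspect",
                RegimeWarning,
                stacklevel=2,
            )

    @classmethod
    def from_s(cls, s: float, N: int) -> "SelectionCoefficient":
        return cls(s=float(s), S=float(2 * N * s))

    @classmethod
    def from_S(cls, S: float, N: int) -> "SelectionCoefficient":
        return cls(s=float(S) / (2 * N), S=float(S))


def selection_from_effect(a: EffectVector, params: ModelParams) -> SelectionCoefficient:
    """Selection coefficient of an allele from its effect vector.

    Selection under the model is blind to direction in trait space: an
    allele's fitness cost is set by the squared length of its effect,
    s = ||a||**2 / w**2, with scaled coefficient S = 2Ns.
    """
    a2 = a.size**2
    if a2 / params.w**2 > 0.1:
        warnings.warn(
            f"a^2/w^2 = {a2 / params.w**2:.3g} > 0.1: effect size is not "
            "small relative to the selection scale",
            RegimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RegimeWarning)
        return SelectionCoefficient.from_s(a2 / params.w**2, params.N)


def load_params(path: str | Path) -> ModelParams:
    """Read ModelParams from a YAML or JSON config with keys {n, w, N, u, L}."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    missing = [k for k in ("n", "w", "N", "u", "L") if k not in raw]
    if missing:
        raise ValueError(f"config {path} missing required keys: {missing}")
    return ModelParams(
        n=float(raw["n"]), w=float(raw["w"]), N=int(raw["N"]),
        u=float(raw["u"]), L=int(raw["L"]),
    )
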
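"""The selection <-> effect-size geometry.

A mutation's fitness cost under multidimensional stabilizing selection
is s = a^2/w^2 where a is the length of its effect vector; its effect on
the focal trait is the first coordinate, with conditional density
phi_n(a1 | a) ~ (1 - a1^2/a^2)^((n-3)/2).  As the number of traits n
grows this tends to a normal with variance a^2/n — already close at
n ~ 10, which is what justifies the chi-square effect representation
used throughout the inference layer.
"""

import numpy as np
from scipy import stats

from quantgen_arch import (
    EffectVector,
    ModelParams,
    effect_cdf,
    effect_density,
    selection_from_effect,
)

params = ModelParams(n=4, w=2.0, N=5000, u=1e-8, L=1_000_000)
a = EffectVector((0.1, 0.1, 0.1, 0.1))
sel = selection_from_effect(a, params)
print(f"effect size a = {a.size:.3f} (trait units), w = {params.w}")
print(f"selection: s = {sel.s:.4f}, S = 2Ns = {sel.S:.0f}\n")

print("phi_n at a1 = 0 (a = 1) versus the normal limit:")
for n in (2, 3, 10, 50):
    d0 = effect_density(0.0, 1.0, n)
    norm0 = stats.norm.pdf(0.0, scale=1 / np.sqrt(n))
    grid = np.linspace(-0.999, 0.999, 2001)
    ks = np.max(np.abs(effect_cdf(grid, 1.0, n)
                       - stats.norm.cdf(grid, scale=1 / np.sqrt(n))))
    print(f"  n = {n:3d}: phi_n(0) = {d0:6.3f}, N(0, 1/n) pdf = {norm0:6.3f}, "
          f"KS distance = {ks:.4f}")
print("\nn = 3 is exactly uniform on (-a, a); by n ~ 10 the normal limit "
      "is a good\ndescription, and effect sizes given selection are "
      "N(0, (w^2/n) s).")
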
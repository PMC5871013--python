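"""Where does trait variance sit on the frequency spectrum?

Computes the expected per-site contribution to additive variance as a
function of the scaled selection coefficient S = 2Ns (in units of v_s,
the strong-selection per-site contribution), and the fraction of that
variance carried by common alleles (MAF > 0.1).
"""

import numpy as np

from quantgen_arch import maf_variance_fraction, variance_ratio_curve

curve = variance_ratio_curve(np.geomspace(0.1, 100, 13))
print("Expected per-site variance, units of v_s = 2w^2/nN:")
for _, row in curve.iterrows():
    print(f"  S = {row.S:7.2f}   E(v)/v_s = {row.ratio:6.3f}")
print(f"\ncrosses v_s at S = {curve.attrs['crossing']:.2f}; "
      f"peaks at S = {curve.attrs['argmax']:.1f} "
      f"({100 * (curve.attrs['peak'] - 1):.0f}% above the asymptote)")

print("\nFraction of variance from sites with MAF > 0.1:")
for S in (3, 10, 100):
    frac = maf_variance_fraction(S, 0.1)
    print(f"  S = {S:5g}: {100 * frac:5.1f}%")
print("\nIntermediate and strongly selected sites contribute similar "
      "variance, but\nonly the intermediate ones do so through common "
      "alleles a GWAS can see.")
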
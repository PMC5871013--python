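"""What a bottleneck followed by explosive growth does to architecture.

Forward-simulates per-site allelic trajectories under a synthetic
bottleneck+growth caricature (this is an illustrative fixture, not an
inferred history): ancestral N = 10,000, a 1,500-generation bottleneck
at N = 2,000, then 200 generations of exponential growth to 100,000.
Standing variation starts at the ancestral equilibrium; new mutations
arrive in proportion to 2N(t)u.

The headline effect: the variance carried by sites whose individual
contributions are large enough to matter for a GWAS peaks at
intermediate selection (s ~ 1e-3) — mutations that drifted up during
the bottleneck and kept their frequency through the growth phase —
while both weaker and stronger selection coefficients contribute less.
"""

from quantgen_arch import Demography, Epoch, ModelParams, variance_by_s_under_demography

params = ModelParams(n=10, w=1.0, N=10_000, u=1.25e-8, L=1_000_000)
demo = Demography(epochs=(
    Epoch(gens=100, N_start=10_000),
    Epoch(gens=1500, N_start=2000),
    Epoch(gens=200, N_start=2000, N_end=100_000, mode="exp"),
))

s_grid = [1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2]
df = variance_by_s_under_demography(s_grid, demo, params, n_events=100_000,
                                    seed=0, thresholds=[1e-4])

print("variance from sites contributing > 1e-4 w^2/n, per target site")
print("(units of 4u*w^2/n, the equilibrium per-site total at strong selection)\n")
print(f"{'s':>8s} {'segregating':>12s} {'above-threshold var':>20s}")
for _, row in df.iterrows():
    print(f"{row.s:8.0e} {int(row.n_segregating):12d} "
          f"{row['cumvar_above_0.0001']:20.3f}")
best = df.loc[df["cumvar_above_0.0001"].idxmax()]
print(f"\npeak at s = {best.s:g}: bottleneck-era mutations at intermediate "
      "selection dominate\nthe detectable variance; strongly selected sites "
      "are young (post-growth) and rare-\nallele dominated, weakly selected "
      "ones have tiny effects.")
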
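# Methods

## Model and assumptions

An individual's phenotype is a point in an n-dimensional Euclidean trait
space; fitness declines with distance r from an optimum at the origin as
exp(−r²/2w²). Only the curvature at the optimum matters near
equilibrium, so the Gaussian form is a convenience, and the additive
environmental variance is absorbed into w. The genetic contribution is
additive over L biallelic sites (infinite-sites regime, θ = 4Nu ≪ 1);
mutation is isotropic in trait space with 1 ≫ U = Lu ≫ 1/2N and effect
sizes a² ≪ w². Anisotropic mutation is handled through the effective
number of traits n_e, a real number ≥ 1 used wherever n appears; no
separate covariance machinery is exposed.

At equilibrium the phenotypic distribution is a tight multivariate
normal at the optimum and sites decouple: each segregating site follows
an underdominant single-locus dynamic with selection coefficient
s = a²/w² (scaled S = 2Ns), drift M(q) = s·pq(q−½) and diffusion
V(q) = pq/2N. We do not reproduce the closed form for the phenotypic
variance σ² (supplement-only in the source literature); the multilocus
simulator measures it instead.

## Sojourn density and architecture statistics

All equilibrium statistics integrate over the diffusion sojourn-time
density of a new mutation entering at q₀ = 1/2N. With scale density
ψ(y) = exp(S·y(1−y)), ψ integrates in closed form through the error
function, and the variance-weighted sojourn collapses to

    pq·t(q) = N·√(π/S)·[erfc(x₀)−erfc(c)]·[erfc(z)−erfc(c)]·e^{z²}/erf(c)

with c = √S/2, z = √S(q−½), x₀ = √S(½−q₀). The implementation
evaluates this expression entirely in log space (log-erfc via
`scipy.special.log_ndtr`), which keeps S in the thousands finite; S = 0
uses the exact neutral forms. Quadrature uses adaptive `scipy` routines
for scalar integrals and a log-spaced-edge + linear-interior grid
(4–6k points) with cumulative trapezoids for the vectorised
region-integral tables behind G(v). The S = 0 (integral = 1) and
S → ∞ (integral = 2/S) analytic corners are asserted in the tests.

Per-site expectations are reported **per new mutation, in units of
v_s = 2w²/(nN)**; multiplying by the influx 2Nu converts to stationary
per-site moments, and ratios such as G(v) and the MAF decomposition are
normalisation-free. In these units the contribution of a site is
v = (S/2)·ε·q(1−q), where ε = n·a₁²/a² is the scaled squared effect:
exactly ε/n ~ Beta(½, (n−1)/2); ε ~ χ²₁ in the pleiotropic limit. The
n = 1 case is the discrete pair a₁ = ±a and is a separate code path
throughout — never a density. The printed normalisation of φₙ is not
trusted: the implementation normalises through the beta function and the
tests verify ∫φₙ = 1 and the second moment a²/n by quadrature (for
n = 2 the integrand is endpoint-singular; the tests integrate under
a₁ = a·sinθ).

G(v) is computed two ways. `G_closed` implements the four corner forms
— exp(−2v) and √(1−v/v_max) with v_max = S/8 for n = 1,
(1+2√v)e^{−2√v} and exp(−4v/S) in the pleiotropic limit — after
resolving radical-sign ambiguities in the transcribed forms against the
mean–survival identities (∫G dv = ½, S/12, 3/2, S/4 respectively).
`G_numeric` is the oracle: nested quadrature of the variance-weighted
survival of v over (q, ε) (or Monte Carlo), valid for any (S, n). Corner
agreement is asserted at sup-difference < 0.01 on v ∈ [0, 5] using
N = 10⁶ so the 1/2N entry boundary does not contaminate the comparison;
the residual ~0.008 at S = 100 is the genuine O(1/S) distance from the
asymptotic regime. One caveat found with the oracle: at the regime split
S ≈ 5 the true curve falls *below* the neutral-limit form for v ≳ v_s
(the q(1−q) ≤ ¼ cap suppresses large contributions at moderate S), so
the curve is only bracketed by the two limit forms at small v.

Regime tags for auto-selection follow S > 30 (strong) and S < 1
(effectively neutral), numeric in between. MAF statistics fold the
integration region (MAF = min(q, 1−q)); stored frequencies are never
folded.

## Forward simulation

`simulate_site` iterates q ← Binomial(2N(t+1), q + s·pq(q−½))/2N(t+1)
from entry at 1/2N(t₀), with origins either at a fixed time or drawn
proportional to the influx 2N(t)u. Population-size histories are
ordered epochs of constant or per-generation-discretised exponential
size (rounded, floored at 2); a constant history split into several
epochs yields the identical N(t) array and hence bit-identical
trajectories under the same seed. The guard |E(Δq)| ≤ ½ rejects s too
large for the discrete update. At N = 1000 the simulator matches the
diffusion per-mutation variance within 2–3.5% across S ∈ {1, 10, 100};
the residual at S = 100 is real binomial/discreteness bias at s = 0.05
and shrinks with N.

`variance_by_s_under_demography` initialises standing variation from
the stationary sojourn density of the first epoch (count-weighted
snapshot) instead of burning in ~4N₀ generations — exact for the
model's equilibrium and cheap — and injects new mutations at rate
2N(t)u; the initialisation is flagged in the output metadata. Sampled
mutation events are weighted so that u cancels from per-site
expectations. Because the effect multiplier ε is independent of the
trajectory with E(ε) = 1, unthresholded means are computed with ε
marginalised out (exact Rao–Blackwellisation; the heavy-tailed χ²₁
multiplier otherwise dominates the Monte Carlo error). Thresholded
quantities (cumulative variance above a cutoff, Fig-style curves)
necessarily use the sampled ε. Under a bottleneck+growth caricature
(ancestral 10k; 1,500 generations at 2k; 200 generations exponential to
100k — an illustrative fixture, not an inferred history) the
above-threshold variance per site is non-monotone in s with an interior
peak near s ≈ 10⁻³: bottleneck-era mutations at intermediate selection
dominate what a GWAS can see. The raw per-segregating-site mean is a
much weaker signal of the same effect because the site count at the
grown population size is dominated by very young, negligible-variance
mutations.

`simulate_multilocus` is a deliberately small individual-based
implementation of the full model (finite-L recurrent sites with fixed
per-site effect vectors as the θ ≪ 1 stand-in for infinite sites; free
recombination; Poisson(U) mutations per gamete) used only to validate
the per-site reduction: the mean stays at the optimum, σ² ≪ w², and
per-site frequency changes regressed on pq(q−½) — recorded *before*
mutation so mutation pressure cannot contaminate the slope — recover
a²/w² within 10% at the test scale (N = 600, L = 400, U = 0.008,
s = 0.02, 2,500 generations).

## Detection model and inference

Power is a step function: a locus is detected iff its variance
contribution exceeds v* = c·V_P/m. The calibration constant defaults to
the χ²(1 df) noncentrality at which a locus is detected with 50% power
at α = 5×10⁻⁸ (c ≈ 29.7, computed at runtime and overridable), since
the expected association statistic of a locus explaining fraction v/V_P
of phenotypic variance is ≈ m·v/V_P.

Among detected loci the model implies, in the strong pleiotropic
regime, a per-locus variance density

    f(v) ∝ exp(−2√(v/v_s)) / v      on v ≥ v*,

whose survival is E1(2√(v/v_s))/E1(2√(v*/v_s)) and whose
variance-weighted survival is exactly the strong-limit
G(v) = (1+2√(v/v_s))e^{−2√(v/v_s)} — the property the tests verify
against both the numeric oracle and the synthetic generator. This
site-count family is the default likelihood (`family="sites"`); it is
improper at v* = 0 (rare tiny-v sites pile up without bound), which is
why a positive threshold is required. `family="variance"` supplies the
variance-weighted density ∝ exp(−2√(v/v_s)) for work with
proportion-of-variance curves, and is proper at v* = 0. Finite-n
variants (ε-mixtures; n = 1 closed via E1) support an `exact-n` mode
that profiles n over a grid — used to check that n = 1 data are not
attributed to the limit and vice versa.

The MLE of v_s is a bounded 1-D optimisation on log v_s. Uncertainty is
by parametric bootstrap with **basic intervals on the log scale**: v_s
and L are scale parameters, so log(estimate/truth) is near-pivotal and
the log-basic interval calibrates better than raw percentiles (measured
95.7% vs 94.7% coverage at 500 loci). Exact samplers exist for every
family (rejection from shifted exponentials with accept probability
v*/v or u*/u; an exponential+Gamma mixture for the variance family).

Goodness of fit is Kolmogorov–Smirnov against the fitted truncated CDF:
`classic` (asymptotic p, comparable to published analyses but
conservative because v_s is estimated from the same data) and
`bootstrap` (refitting each parametric resample; calibrated — the test
suite checks the resulting p-values are uniform under the null).

Target size: the expected number of detected loci is
L·2Nu·C(v*/v_s) with C(x) = E_ε[2·E1(2x/ε)], the strong-limit
per-mutation sojourn count above threshold, so the observed count gives
L̂. The detectable fraction of heritability is L̂·2Nu·v̂_s/(h²V_P), and
projections use explained(m) = detectable_fraction · G(v*(m)/v_s) and
hits(m) = L̂·2Nu·C(v*(m)/v_s), both saturating as m → ∞.

## Synthetic data

`generate_architecture` draws, per site, S from a user distribution
(point mass or weighted table — the model itself leaves this free), q
from the normalised sojourn density (an equilibrium snapshot of
segregating sites, not a trajectory simulation; demography-aware tables
come from the simulator), and a₁ from the effect geometry; v = 2a₁²pq.
`generate_gwas_table` thresholds at v*(m) and emits (snp, freq, beta)
with 2β²pq = v exactly; optional effect-estimate noise
N(0, V_P/(2m·pq)) is off by default, matching the assumption that
reported variances faithfully reflect the causal loci. Tables carry the
seed and a spec hash in their comment header.

What the generator emulates — and what it does not: it reproduces the
model's exact joint (q, a₁) law at equilibrium, so passing round trips
demonstrate internal consistency of the inference, not robustness to
linkage disequilibrium, winner's curse, per-locus power that is not a
step function, population structure, or non-equilibrium demography.
Those failure modes must be judged externally. Published height/BMI
tables are read through the same TSV reader but are not bundled and
their headline numbers are not reproduced offline.

## Numerical and testing choices

Default study conditions in the tests: N = 10⁴, u = 1.25×10⁻⁸, n = 10,
w = 1 (so v_s = 2×10⁻⁵ in V_P units), Mb-scale targets; round trips use
~500–3,000 detected loci at v*/v_s ≈ 0.3, the regime of current large
GWASs. Simulation sizes were chosen so Monte Carlo error sits well
below each assertion's tolerance: 10⁶ replicates for the
simulator/diffusion comparison (the per-mutation variance estimator is
heavy-tailed; at 10⁵ replicates its seed-to-seed spread of ~9% would
exceed the 5% check), 10⁵ mutation events for the demographic toy, and
400 replicates × 300 bootstrap draws for the CI-coverage assessment
(binomial noise of a 100-replicate assessment is comparable to the
margin being asserted). All randomness flows from explicit seeds;
repeated runs are bit-identical.

Known limitations: free recombination and no dominance/epistasis by
construction; equilibrium theory only (the simulator, not the analytics,
covers non-equilibrium histories); the strong-limit fit family is
measurably biased when the generating selection is only moderately
strong (S ≈ 100 gives v̂_s ~3% high at few-thousand-loci precision);
the step-function power model ignores incomplete power above v* and
winner's curse below it; target sizes in Mb use a reporting convention
of 10⁶ sites per Mb.
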
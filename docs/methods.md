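# Methods

## Model

Hotspot-motif erosion is modeled as a Poisson random field of new
mutations at motif informative sites. A mutation disrupting an active
motif enjoys a transmission advantage through biased gene conversion that
is formally equivalent to genic selection on a semidominant allele: a
heterozygote transmits the disrupting allele with probability (1+g)/2, so
the expected per-generation frequency change is g·x(1−x) and the natural
population-scaled parameter is G = 4·Nₑ·g. Throughout the package G is
*the* scaled drift coefficient: the sojourn density, the fixation
probability, the conditional fixation time and the forward Wright–Fisher
simulator all share this one convention, and the test suite verifies their
mutual consistency by simulation. (Under conventions in which the
heterozygote receives half the homozygote advantage, all diffusion
results correspond to ours evaluated at G/2; predicted fixation times are
then roughly twice as long at strong drive. We keep the single-G
convention because it is the one under which the spectrum likelihood,
fixation probability and simulator agree exactly.)

The expected time a new mutation spends at population frequency x before
absorption is

    H(x, G) = 2 (1 − e^{−G(1−x)}) / (x (1−x) (1 − e^{−G})),   H(x, 0) = 2/x.

With sample sizes of thousands of chromosomes the binomial sampling layer
is collapsed onto the true frequency (continuous approximation); the test
suite checks that this matches the exact binomial-sampled expectations to
<0.5% on interior frequency bins at n = 200. The approximation is least
accurate in the top frequency bin at intermediate G, where the binomial
smearing width (~1/√n) is comparable to the e^{−G(1−x)} boundary layer
(deviation ~0.8% at n = 200, G = 10).

Observed bin counts for a neutral reference class (control-motif
mutations) and a test class (hotspot-motif mutations) are independent
Poisson draws with means r_j·θ_c·∫_bin H(x, G_c) dx. The per-bin
distortions r_j (r₁ = 1, shared between classes) absorb demography,
population structure and sampling; θ_c is a per-class mutational input
(2·Nₑ·u·L analog). Model M0 fixes G = 0; M1 fits one constant G ≥ 0; the
proportional model sets G = c·X with X the local crossover rate, gamma-
distributed across motifs with shape inherited from the observed rate
distribution, and optimizes c only.

## Inference

*Nuisance profiling.* For fixed G the likelihood is concave in the logs of
(θ_N, θ_T, r), and each coordinate update has a closed form; exact
coordinate ascent therefore finds the global conditional optimum
(tolerance 1e-10 on lnL). G is profiled on a log grid spanning 1e-2–1e4
plus G = 0, then refined by bounded scalar optimization.

*Testing.* The likelihood-ratio statistic for conversion compares M1 to
M0. Because G = 0 lies on the boundary of the parameter space, the
statistic's null distribution is the 50:50 mixture of a point mass at zero
and χ²(1) rather than plain χ²(1); we report the mixture p-value, which
makes the nominal 5% level hold to within Monte-Carlo error in
simulation (a plain χ²(1) reference would be conservative by a factor of
two). The raw statistic is reported alongside, so any other reference
distribution can be applied. Goodness of fit is the deviance against the
saturated model (every bin mean free), with degrees of freedom equal to
the number of nonempty count cells minus the number of fitted parameters;
it is reported, not auto-rejected.

*Intervals.* Confidence bounds are the G values at which the profile
log-likelihood (nuisances re-optimized at every G) falls two points below
its maximum, corresponding to ~95% coverage; simulated coverage at G = 1
and G = 10 is consistent with 95%. A fixed-nuisance variant (all other
parameters pinned at the joint optimum) is available via
`profile_nuisance=False`. Expected spectra become nearly invariant in G
above ~20 — the free r_j absorb what little shape difference remains — so
upper bounds can legitimately be very large or infinite; an infinite upper
bound is reported as such rather than clipped.

*Bins.* Default spectrum bins are a rare-variant bin [1/n, 0.01) plus m
equal-width bins on [0.01, 1), m = 5 by default; estimates are stable
across m ∈ {5, 10, 20} (overlapping intervals on shared data). Fixed
changes (DAF = 1) are excluded from the likelihood — the field describes
segregating mutations — and carried separately in descriptive output.
The first edge must be positive since H is not integrable at 0.

## Numerics

∫ H dx over a bin is computed by composite Gauss–Legendre quadrature in
log-x, with panel boundaries placed geometrically from both bin ends (to
resolve the 1/x and 1/(1−x) factors) and at 1 − c/G for c ∈ {50, 5, 0.5,
0.05} (to resolve the exponential boundary layer at large G); a final
sliver above 1 − 1e-12 is added analytically via H → 2G/(1 − e^{−G}).
Relative accuracy is ≤1e-8 up to G = 1e5, verified against adaptive
quadrature. Integrals are cached keyed on (G, bin edges), which makes the
repeated fits in calibration studies cheap. Expectations under a gamma law
of G use 48-node Gauss–Legendre quadrature on the quantile scale.
Exponential differences are evaluated with `expm1` everywhere, so the
G → 0 limits are exact to machine precision.

The conditional mean fixation time of a new mutant follows from the
diffusion Green's function with drift G·x(1−x)/(4N) and variance
x(1−x)/(2N):

    t* = 4N / (G (1 − e^{−G})) ∫₀¹ (1 − e^{−Gx})(1 − e^{−G(1−x)}) / (x(1−x)) dx,

with neutral limit 4N. The integrand is bounded (→ G(1 − e^{−G}) at both
endpoints); adaptive quadrature is split at the 1/G-scale boundary layers.
The Wright–Fisher simulator reproduces this formula and the fixation
probability (1 − e^{−G x₀})/(1 − e^{−G}) within Monte-Carlo error across
G ∈ {0, 2, 20}, N ∈ {500, 1000}.

Motif-loss probability over T generations is
P(G) = 1 − exp(−µkT·G/(1 − e^{−G})) with defaults µ = 1.2e-8 /bp/gen
(human pedigree estimate), k = 11 disruptible positions, T = 1e5
generations. Note P is convex in G near 0 and concave only beyond the
saturation knee (G of a few units), so Jensen-type bounds on E[P(G)] hold
on upper tails but not globally. Averages over a gamma law of G use
adaptive quadrature on the quantile scale (relative tolerance 1e-6), with
any zero-recombination point mass mapped to G = 0. Tail calibration
(choosing the gamma mean so that the conditional mean above a quantile
hits a target) exploits the scale-family monotonicity and solves by
bracketed root-finding.

## Equilibrium GC content

GC* on a branch is the flux ratio f_WS/(f_WS + f_SW) with f_WS = n(W→S)/
n(W) and f_SW = n(S→W)/n(S), base counts taken at the branch's ancestral
node. Potential CpG sites are masked first: within each of the four
aligned sequences, a C followed by a G masks both positions, and the final
mask is the union over sequences. The union semantics is deliberately
conservative; because it also masks CpGs *created* by W→S substitutions,
it depresses GC* below the purely mutational expectation — the estimator's
property tests therefore validate against the closed-form expectation with
masking off, and separately assert that masking only removes counts.
Spatial profiles pool substitution and opportunity counts across anchors
per offset bin (10 bp dots, 500 bp rolling smoothing) before applying the
flux formula — a ratio of pooled counts, since 10-bp windows rarely
contain a substitution; the alternative (mean of per-anchor ratios) is
undefined almost everywhere at that resolution. Windowed GC*-vs-
recombination regressions use ordinary least squares on 1-Mb windows (or
a configurable size), requiring ≥10 usable windows.

## Branch assignment and loss accounting

With a resolved Denisovan base: a site mutates on the chimpanzee branch
iff ancestor ≠ chimpanzee; on Hominini iff human = Denisovan ≠ ancestor;
on a terminal branch iff that lineage alone differs; sites where human and
Denisovan carry two distinct derived states are excluded, and motifs
containing such a site are dropped. A motif lost on Hominini is absent
from the human–Denisovan ancestor and leaves the terminal denominators.
Heterozygous genotypes are resolved uniformly at random; loss counts are
averaged over R = 100 resolutions by default, with the spread (SD,
min–max) reported. Stratification (hotspot, THE1-like, rate terciles) uses
the any-overlap rule between the 13-bp motif interval and the track.
Proportion contrasts use the pooled-variance Z-test with Yates continuity
correction.

## The synthetic-data generator

The generator emulates the study conditions: 4,440 hotspot and 4,393
control motifs, n = 2184 sampled chromosomes, ~500 segregating mutations
per class (θ = 32.5), conversion intensity G = 8.55 on hotspot motifs,
per-branch substitution rates chosen so control-motif loss rates match the
observed cascade (~5.3% chimpanzee, ~4.5% Hominini, ~0.5% Denisovan,
~0.4% human across 10 informative sites), annotation error rates tuned so
F1/F2/F3 motif retention follows the observed ~96%/78%/~45% pattern, a
crossover-rate gamma law (mean 5.02 cM/Mb, shape 0.28) with planted 2-kb
hotspot intervals, and a strong/weak substitution-direction bias inside
hotspot windows (defaults: 0.5 on the human branch, 0.1 on Hominini)
applied at fixation. The ancestral sequence is i.i.d. with GC fraction
0.4; substitutions follow a single-parameter symmetric model whose
stationary GC under bias b has the closed form used by the GC* recovery
tests. Allele-frequency tables combine reference-visible substitutions
(a configurable fraction fixed) with reference-invisible segregating
variants drawn from H(x, G) by inverse-CDF sampling. All randomness flows
from one root seed through named, independently hashed streams, so every
artifact is byte-reproducible.

What the generator does *not* emulate: linkage and LD between sites,
coalescent noise in allele frequencies (bin counts are Poisson draws from
the field expectations, so fit calibration tests exercise the estimator
under its own model), realistic human demography (absorbed into r_j, which
default to 1), alignment errors beyond i.i.d. annotation flags, indel
processes, and the physical compression of intergenic space (motifs are
planted every ~1 kb, so interval tracks cover a larger genome fraction
than in real data). Passing tests therefore demonstrate correctness of the
estimators under their stated model and exact bookkeeping of the
branch/filters/loss machinery — not robustness to model misspecification
on real genomes.

## Problem sizes in the test suite

Calibration studies use 1,000 null spectra for test size, 150 replicates
per G for interval coverage, ≥2,000 fixations per setting for the
Wright–Fisher comparisons, and full-scale (8,833-motif) quartets for the
end-to-end recovery checks; these sizes give Monte-Carlo standard errors
several times smaller than the tolerances asserted.

## Known limitations

- The continuous approximation degrades in the highest-frequency bin for
  moderate G (see above); with default binning the effect is negligible at
  n ≈ 2000.
- Ĝ is strongly right-skewed at realistic mutation counts; point estimates
  at ~300–500 mutations per class can be off by a factor of ~2–3 even when
  intervals cover the truth, and upper bounds are unbounded whenever the
  data cannot distinguish G from ∞ (expected beyond G ≈ 20).
- GC* under the conservative CpG mask is biased low relative to the
  mutational equilibrium; comparisons should be within-mask only.
- The lifespan predictions inherit the gamma approximation to the
  crossover-rate distribution; a zero-inflated or heavier-tailed empirical
  distribution shifts the genome-wide average loss fraction by several
  percentage points while leaving the upper-tail prediction nearly
  unchanged.
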
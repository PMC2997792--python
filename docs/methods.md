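# Methods

`pinepop` reimplements, as a tested library, the population-genetic analysis
pipeline used in candidate-gene surveys of loblolly pine (*Pinus taeda*)
with Scots pine (*P. sylvestris*) as outgroup: demographic inference from
folded site-frequency spectra by Monte-Carlo ARG likelihoods, per-locus
neutrality scans against simulated nulls, hierarchical Bayesian
McDonald-Kreitman / Poisson-random-field (MKPRF) selection inference, and a
Wakeley-Hey-style two-species isolation-model analysis of shared
polymorphism. This note records the models, unit conventions, numerical
choices, and the places where the design was genuinely open.

## Unit conventions

* **Within-species demography.** Time is measured in units of `2 N_0`
  generations, sizes as ratios to the current effective size `N_0`
  (piecewise-constant epochs, instantaneous changes). The per-locus scaled
  mutation rate is `Theta = 4 N_0 mu L`; per-frequency-class branch lengths
  `b_i` are scaled so `E[x_i] = b_i * Theta`, giving `E[b_i] = 1/i` under
  constant size. The scaled recombination rate `rho = 4 N_0 r` per bp
  (default 0.023/bp, the study system's genome-wide estimate) enters as
  `rho * (span) / 2` per lineage per time unit.
* **Isolation model.** Species 1 is the reference: `theta1 = 4 N_1 mu` per
  locus, `theta2/theta1` and `thetaA/theta1` are size ratios, and the
  divergence time `tau` is reported in coalescent units of `4 N_1`
  generations (the scaling used by ms-style simulators). The published
  divergence-time estimate for the pine pair (printed as "0.86 N_1
  generations") is reproduced on this 4-N_1 scale; the printed unit label is
  internally inconsistent with the same source's `tau = 2 mu t` definition,
  and the 4-N_1 reading is the one consistent with the printed per-locus
  expected counts (see below).
* **Wright-Fisher forward simulation** resamples `N` haploid gene copies
  binomially and reports absorption times in units of the
  diploid-equivalent effective size `Ne = N/2`; on that scale the diffusion
  prediction for a neutral allele at frequency `p` is
  `-4[p ln p + (1-p) ln(1-p)]` (4 ln 2 = 2.77 at `p = 1/2`).

## ARG simulation and the SFS likelihood

The engine is a Hudson-style back-in-time coalescent with recombination
over `L` discrete sites. Each lineage stores, per site, the set of sampled
sequences it subtends (a 64-bit mask; sample sizes up to 64); coalescences
merge masks, recombination splits carried material at a breakpoint chosen
uniformly inside the lineage's ancestral span (trapped non-ancestral
material recombines, as it must). A site stops accruing branch length at
its marginal MRCA. The per-class output `b_i` is the per-base average over
sites. A numba-compiled kernel implements the same algorithm for the
branch-length-only path (independent random stream; the pure-Python core
remains as fallback and for mutation-pattern generation). Agreement with
closed forms (`E[b_i] = 1/i`) and with an independent coalescent simulator
(msprime branch-mode frequency spectra under a bottleneck) is enforced by
tests.

Given an ARG, the probability of an observed spectrum is a product of
independent Poisson densities with rates `b_i * Theta`; the model
likelihood averages this product over `M` simulated ARGs. Averaging is done
in log space (overflow-safe log-mean-exp); an ARG with `b_i = 0` where
`x_i > 0` contributes likelihood zero, handled naturally by the reduction.
Folded spectra are evaluated against folded rates `b_i + b_{n-i}`
(`b_{n/2}` unchanged for even `n`) — the exact consequence of Poisson
additivity, not an approximation. Loci are unlinked, so the dataset
log-likelihood is the sum over loci; ARG streams are shared across loci
with identical sample size and length.

Watterson's estimator is biased under non-equilibrium demography by a
factor that depends on the model but not on `Theta`; the factor is
estimated by simulation at a known rate and divided out of the
class-averaged per-site estimates (coding and promoter classes averaged
separately, since promoters in this system are roughly twice as diverse).

## Demographic model search

Model classes are nested: constant size, two-epoch (one change at `T_A` to
`N_A/N_0`), and three-epoch bottleneck (`N_B/N_0` between `T_B` and `T_A`;
combinations with `T_A <= T_B` are invalid). Grids are full-factorial and
log-spaced with endpoints included; the published coarse ranges
(`T in [0.01, 4]`, `N/N_0 in [0.01, 100]`, 15 points) and fine ranges are
the defaults. The staged protocol — coarse (3 averaged evaluations) →
fine (3 averaged) → deep re-evaluation of all models within 4 log-units
(10 averaged) — is implemented as published, but the default `M` values
and grid sizes in the CLI are desk-scale; the published `M = 10^4/2*10^4/
10^6` protocol over ~10^5 models is a cluster-scale computation reachable
by configuration only. Nested classes are compared by likelihood-ratio
tests with `2 * delta-log-likelihood ~ chi-square(df = 2)`. The published
grid-size counts (30,875 / 273 / 154,800 models) are not reproducible from
the stated point counts and are not treated as contracts.

For the parameter-recovery validation (60 synthetic loci, 5-point
factor-of-two grids around a strong bottleneck), the likelihood of every
grid point is evaluated with a common-random-number ARG stream seed, a
standard variance-reduction device that stabilises the argmax without
raising `M`. Synthetic loci in that test are represented at 250-site
resolution with per-site rates chosen so the per-locus totals
(`theta_L = 4`, `rho_L = 5.75`) match multi-hundred-bp loci at study-like
rates; sampling properties depend on the scaled totals, not the site count.

## Neutrality scan

Observed per-locus statistics (segregating sites `S`, Tajima's D, Fu & Li's
D*) are compared against empirical null distributions from loci simulated
under the best-fit demography at the class-average corrected rate times
locus length — deliberately *not* the locus's own estimate, so that
diversity deviations remain detectable. The reported quantile is the
proportion of simulated values strictly less than the observed value (ties
count as not-less); two-sided flags at alpha = 0.05 / 0.01 / Bonferroni
split the level between tails. Replicates with `S = 0` are excluded from
D-statistic nulls and their frequency reported.

Two facts worth knowing when reading scan output: Fu & Li's variant is D*
(total singletons, no outgroup required) by default, with outgroup-aware D
available when ancestral alleles exist, and the variant is recorded; and
Tajima's D has a small negative expectation under strict neutrality
(about -0.10 at n = 20, theta = 5, confirmed against an independent
simulator), so quantiles — not nominal zero — are the reference.

## MKPRF

Counts per locus follow the Poisson-random-field sampling theory with
scaled selection coefficient `gamma = 2 N s` on replacement sites:

    E[Ps] = theta_s * a_{n-1}          E[Ds] = theta_s * tau_div
    E[Pr] = theta_r * P(gamma, n)      E[Dr] = theta_r * tau_div * F(gamma)

with `F(gamma) = 2 gamma / (1 - e^{-2 gamma})` the relative fixation rate
and `P(gamma, n)` the sojourn-density sampling integral (adaptive
quadrature to 1e-8 relative tolerance; equal to the harmonic number
`a_{n-1}` at `gamma = 0`). These forms are reconstructions from the
standard PRF theory — the source analysis names the hierarchical structure
but prints no equations. The hierarchy is `gamma_l ~ Normal(mu_g,
sigma_g^2)` within locus groups, with a diffuse normal prior on `mu_g` (sd
10), inverse-gamma on `sigma_g^2` (2, 1), diffuse Gamma(0.01, 0.01) priors
on `theta_s`, `theta_r`, `tau_div`. Sampling is Metropolis-within-Gibbs:
the rate parameters and `tau_div` are conjugate Gamma draws, the `gamma_l`
take a vectorised random-walk Metropolis step (proposal sd 0.8) against a
cubic-spline interpolant of `log P(gamma, n)` (quadrature-exact nodes every
0.25 on [-30, 30]), and the group hypers are conjugate. Convergence is
monitored with the Gelman-Rubin potential scale reduction factor across
independent chains; non-convergence flags the result. The published MCMC
protocol (10 chains, 10,000 burn-in, thin 10, 10,000 samples/chain) is the
default configuration; validation tests use shorter, converged runs. A
locus is called "significant" when >= 95% (or 99%) of posterior draws for
its selection coefficient fall on one side of zero. Correctness is defined
by calibration and recovery properties (sign recovery of group means,
~95% credible-interval coverage on neutral tables), not by matching any
particular sampler's trajectories.

## Isolation model

Expected counts of the four polymorphism categories — exclusive to species
1 or 2, shared, fixed — are computed *exactly* under the isolation model:
the within-species phase via the lineage-count distribution of the Kingman
death chain (matrix exponential; the time-integrated occupancies come from
the block `[[Q, I], [0, 0]]` trick), the ancestral phase via exchangeable
subset-subtending branch lengths (`2 rA / i` split over the `C(m, i)`
subsets of the surviving lineages). The expectations were validated against
msprime to Monte-Carlo precision. Fitting equates the four observed
category totals (summed over loci) with their expectations — method of
moments, solved by bounded log-scale least squares; categories with zero
observed totals enter on the linear scale. Loci differ in outgroup sample
size: with a single outgroup gamete, outgroup-exclusive and shared
categories are structurally impossible, which materially changes the fit
when outgroup sampling is uneven (the bundled pine table encodes n2 = 1
for the seven loci whose published per-locus expectations are exactly zero
in those categories).

Per-locus expected quadruplets are the model's category proportions for
that locus's sample sizes scaled by the locus's observed total (the total
acts as the relative mutation-rate estimate, exactly the convention of the
published per-locus table; expected and observed totals then agree by
construction and the G-test probes the partition). Deviations use
`G = 2 sum O ln(O/E)` with zero-observed cells contributing nothing, and a
chi-square tail at df = 4 — following the published table, although four
cells would conventionally give df = 3 — with Bonferroni multiplication by
the locus count.

Two calibration caveats are inherent to this procedure and documented
rather than hidden. First, without intra-locus recombination the four
categories share a single genealogy, making counts strongly correlated and
the raw df = 4 test anti-conservative under the model itself; with
study-like recombination (`rho = 0.023/bp`, multi-hundred-bp loci) the
simulated G distribution matches the published non-significant rows (mean
G ~ 5) and the Bonferroni rule — the decision criterion actually used — is
conservative. The isolation simulator therefore supports intra-locus
recombination (two-population ARG; category means are recombination-
invariant, which tests verify). Second, the global goodness-of-fit
quantile is a plug-in parametric bootstrap (no refitting inside), with a
two-part Pearson statistic: per-locus partitions conditioned on locus
totals, plus the four global totals against their unconditioned
expectations. The global part is what flags datasets whose totals the
model cannot reproduce at all — a pathology that per-locus terms alone
miss, because refitting to grossly aberrant data drives the four moment
equations to absorb the aberration into an extreme ancestral size.

## Synthetic data

Generators emulate the study design: ~70 unlinked loci of 500-2000 bp in
two diversity classes (promoter per-site theta 0.008, coding 0.004 —
promoters about twice as diverse, at levels typical for this system),
`rho = 0.023/bp`, 32 ingroup and 2 outgroup haploid gametes, the
best-supported three-epoch bottleneck (85% reduction at `T_B = 0.041`,
ancestral size 3.8x at `T_A = 0.214`) for the within-species history, and
isolation-model parameters near the fitted pine values. Sequences drop
infinite-sites mutations (collisions re-drawn) onto a random
uniform-composition reference; coding loci carry one forward-strand ORF
over 80% of their length. Truth manifests record every mutation's site,
carrier set and (for two-species loci) category, so round-trip tests are
exact. What the generator does *not* emulate: base-composition and codon
usage structure, sequencing error and alignment artefacts, indel
polymorphism (masked columns in real data), linked selection, and
population structure — so passing recovery tests demonstrate correctness
of the inference machinery under the model, not robustness to those
real-data complications. PRF count tables are drawn directly from the PRF
Poisson model (selection enters only there, not in sequences).

## Degenerate inputs and tie-breaks

Statistics are flagged undefined (not zero) when `S = 0`; tri-/tetra-
allelic sites are retained but excluded from SFS and category counting;
sites with missing data are down-weighted per-site for diversity
statistics and excluded from the SFS (frequency classes require the full
sample); quantile ties count as not-less; grid ties report all models,
ordered lexicographically; codon classification uses the alignment
consensus for context positions and returns an unavailability flag when
the codon spans masked columns.

## Known limitations

* The moment fit uses category totals only; per-locus information enters
  through the goodness-of-fit stage, not the estimator.
* The MKPRF priors are reconstructions ("diffuse, uninformative"), not the
  original program's exact settings; posterior summaries are validated by
  calibration, and group comparisons are robust to reasonable prior widths.
* The full published demographic search is not run by default (cluster
  scale); correctness of the search machinery is established at reduced
  grid/M with known truth.
* Sample sizes above 64 haploid gametes per locus are unsupported by the
  bitmask engine (the study's maximum is 34 including outgroup).
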
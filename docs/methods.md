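# Methods

## Model and assumptions

Fitness is relative fitness *w* against a common ancestor, defined from
head-to-head serial-transfer competitions as the ratio of natural logs of
each competitor's realized (net fold) growth; *w* = 1 is neutrality. The
null model of no interaction is multiplicative on *w*: the expected fitness
of a mutation combination is the product of its single-mutant fitnesses
measured in the same environment. Absolute epistasis ε is the observed minus
expected fitness, a signed, dimensionless quantity on the fitness scale.
This choice — additive deviations around a multiplicative expectation —
matches how such landscapes are analysed in experimental microbial
evolution, and all uncertainty propagation and t-tests operate on the *w*
scale. Replicate SDs use the n−1 denominator so they feed t-tests with
df = n−1.

Net higher-order epistasis is defined by inclusion–exclusion over subsets:
the net term of a pair is its absolute epistasis, and for |g| ≥ 3 the net
term is ε(g) minus the net terms of all proper subsets with ≥ 2 mutations.
Two properties follow by construction and are enforced by tests: the
decomposition is exact (w_obs = Π singles + Σ ε_net over subsets) and
order-independent, and on a purely multiplicative landscape every term is
zero to machine precision.

## Error propagation

The propagated SD of the expected fitness combines the single mutants'
*relative* errors; the default combination is root-sum-of-squares
(quadrature), the standard first-order propagation for a product of
independent measurements, giving σ_exp = w_exp·√Σ(σ_i/w_i)² and
σ_ε = √(σ_obs² + σ_exp²). A `linear` option sums the relative errors
instead (σ_exp = w_exp·Σσ_i/w_i), a deliberately conservative variant some
descriptions of product-error propagation use; both are exposed through
`error_propagation` configuration because published analyses are often
ambiguous about which was applied. Note the SDs entering the propagation
are replicate SDs, not standard errors of the mean, so the resulting
t-intervals are conservative.

Significance of ε uses t = ε/σ_ε with df = n_reps(observed genotype) − 1,
two-sided, α = 0.05 by default. Per-genotype calls apply no
multiple-testing correction by default; Bonferroni and Benjamini–Hochberg
are available. A zero σ_ε (possible with degenerate replicates) flags the
record rather than reporting p = 0.

## Paths, steps and peaks

Selective accessibility defaults to strict increase of mean fitness at
every step (ties inaccessible); a `significant` mode instead requires each
step to be significantly beneficial at α. Per-edge statistics use
Δw = difference of means, σ_Δ in quadrature, and df = min(n_from, n_to) − 1
— the simplest df consistent with the per-genotype t construction; edge
classification corrects over all L·2^(L−1) edges with Bonferroni by
default. Only mutation-gaining edges are considered (no reversions).
Local peaks use ≥ against all Hamming-1 neighbours, so plateau members all
count as local maxima; exact ties for the global maximum are reported as a
set (ties at 1e-15 resolution).

## Factorial ANOVA and variance partition

The G×E decomposition fits a fixed-effects full-factorial model with
effect-coded (±1) mutation indicators and environment. Effect coding makes
the 63 term columns mutually orthogonal on a balanced design, so per-term
sums of squares are well defined; they are computed sequentially via QR with
terms ordered by ascending interaction order, which reproduces the
orthogonal decomposition exactly when balanced and degrades to a documented
Type-I analysis (with a warning) when not. The ±1 coding restricts the
environment factor to one or two levels; more environments raise an error
rather than silently changing the contrast structure. The variance
partition reports raw SS shares of the total (not variance components),
the scale on which "G×G×E explains ~8% of fitness variance" statements are
made; fractions sum to 1 with the residual.

With the default 5 replicates per cell, a two-environment run has 320
observations and residual df 256 (the historical design this emulates had
325 and df 261; the replicate layout behind that count is unpublished, so a
uniform 5 was chosen).

## Respiration screen

Kinetic curves are summarised by average height h (trapezoidal integral
divided by window length; whether the instrument convention is a mean
height or a rescaled area is not documented, so the time-weighted mean was
chosen and is easy to swap). The differential rule reads "more than 3
standard deviations of the means of h for both strains" conjunctively —
|mean_A − mean_B| must exceed k·SD of *each* strain — the most conservative
consistent reading; the multiplier k (default 3) and a disjunctive variant
are configuration. With duplicate plates the SD of two values has little
power, and a zero SD degenerates the rule to "any nonzero difference"; such
calls carry a `degenerate` flag.

## Synthetic generator

The generator inverts the analysis model: true fitness is the product of
per-environment single-mutant factors plus planted net interaction terms,
replicates add Gaussian noise on the *w* scale (truncated positive by
resampling), and every output is a pure function of (spec, seed). Defaults
mirror the emulated study design: five loci in fixation order, three
environments (the selection environment and the two with the most extreme
opposing effects on the full mutant) with the published single-mutant
factors; 5 replicates; noise SD 0.03, typical of competition assays.
Default pairwise terms follow a diminishing-returns rule
ε_net(pair) = −c·(w_exp(pair) − 1) with weak strengths (c = 0.10, 0.08,
0.15 per environment) so per-pair deviations are a few percent and the
full mutant's summed epistasis stays small against its overall fitness
gain, plus one environment-specific antagonistic pair (t,g: −0.2 in the
fitness-raising environment) that creates G×G×E by construction.

`gxgxe_spec` builds a two-environment spec whose G×G×E class holds an exact
target share (default 8%) of the noise-free model SS: one pair coefficient
takes +d/−d across the environments and d is calibrated by root-finding
against a Walsh (Hadamard) spectrum of the cell means — an independent
spectral route to the same decomposition the ANOVA estimates, also used as
the oracle in recovery tests. Recovery from noisy replicates uses
residual-bias-corrected SS (SS_class − df_class·MS_residual) so the
estimator is approximately unbiased.

Assay generators invert the assay formulas: competition counts reproduce
the target w exactly through the log-ratio (ancestor realizes
dilution^days net growth); growth curves are logistic with initial OD a
fixed 1% of capacity, making each strain's curve an exact scalar multiple
of the ancestor's so AUC ratios equal planted relative growth; respiration
screens plant gains/losses as fold-changes with unplanted wells copied
between strains, so screen counts are exact by construction. What the
generator does **not** emulate: count (plating) noise in competitions,
lag/rate variation among growth curves, non-Gaussian or
fitness-dependent measurement error, and missing cells. Passing
recovery tests therefore demonstrate correctness of the statistics under
the stated noise model, not robustness to those real-data complications.

## Numerical choices and problem sizes

Tolerances: exact identities (reconstruction, multiplicative-null zeros)
are asserted at 1e-12; SS conservation at 1e-9 relative. Path-oracle
agreement runs 100 random landscapes × 120 orderings; planted-recovery
checks use 200 simulated replicated landscapes; the acceptance script uses
50 landscapes for the G×G×E recovery and 100 for interaction-coefficient
coverage — sizes chosen to keep the whole validation in seconds while
leaving simulation SEs well inside the asserted margins. CSV outputs are
serialized at 6 significant digits for reproducible diffs; statistics
recomputed from serialized tables agree to that precision, not bitwise.

## Known limitations

Fitness-lowering environments with strong planted antagonism can have zero
accessible paths, which is informative but makes accessibility counts an
insensitive readout there. The ANCOVA drop-term F-tests assume homoscedastic
Gaussian residuals across strata; the group comparison is a pooled-variance
t-test by design (df = n1+n2−2). The factorial ANOVA is fixed-effects only —
no REML/variance-component estimation — and sequential SS make unbalanced
results order-dependent. Genotype labels restrict loci to single characters
(excluding '0'/'1' to keep bitstrings unambiguous).
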
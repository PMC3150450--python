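# Methods

This note defines the models and estimators implemented in `coevo`, the
defaults they ship with, and the numerical and design choices behind them.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The experimental system being modelled

A lytic RNA phage (Qβ) and *E. coli* are cocultured in glucose-limited
minimal medium and transferred daily: the culture is diluted back to a
target OD600 (≈0.05) and regrows to a stationary plateau of OD ≈ 0.4
(≈3×10⁸ CFU/ml). In the phage-only control regime, the phage is instead
harvested daily and used to infect a fresh exponential culture of the
ancestral host at ≈10⁷ PFU/ml for ≈6 h. Daily titres, hourly infection
time courses, cross-coculture fitness assays and whole-population
resequencing at chosen generations are the data types the analysis modules
consume.

## Generation counting

Replication generations follow the doubling relation N_f/N_i = 2^g, so one
passage contributes g = log₂(N_f/N_i) and the lineage total is the prefix
sum. For passage d > 1 the initial density is reconstructed as
N_f(d−1)/dilution_factor(d); the stored day-1 initial density is used as
is. The estimator deliberately reproduces the field convention: during
heavy early lysis, CFU-based cell generations undercount true divisions
(lysed cells are invisible), and no correction is applied.

## Fitness statistics

Host fitness is log₁₀(OD600 at 7 h / 0.03), the initial OD of the assay
protocol. Phage fitness is log₁₀(max(PFU at 7 h, PFU at 22–29.5 h)/PFU at
0 h); the late read catches slow amplifiers. Fitness is computed per
replicate and assembled unaggregated into hosts × phages grids; how
replicates enter a downstream ANOVA (individually vs averaged) is the
caller's explicit choice, since assay conventions differ on this point.

## Kinetics estimators

All rates are ordinary least squares on ln(value) versus time ("semi-log
fits"), with r² the squared Pearson correlation on the log scale — the
convention under which such rates are reported alongside r² in the source
experiments. Zero values cannot enter a log fit; they are excluded and
counted on the returned fit, never imputed.

- **Specific growth rate** μ (1/h): same fit on OD600 or total-cell
  series. When no window is given, the maximal prefix below 40% of the
  plateau (mean of the final three points) is used and reported; the
  fitting windows of the original growth curves are not recorded anywhere,
  so the window is always part of the result. For *parameter-recovery
  validation* a stricter scenario is used: a dilute inoculum (10⁵
  cells/ml at K = 3×10⁸) fitted on the prefix below 10% of the plateau,
  because the logistic correction (1 − N/K) biases a semi-log slope by
  several percent once the fit window climbs toward K/4. The 2% recovery
  tolerance is attainable only in that early-exponential regime.
- **Time to stationary**: earliest linear-interpolated crossing of
  (1 − ε)·plateau with ε = 0.05 by default; the final three points must be
  flat to within ε, otherwise the culture never saturated and the estimate
  is undefined.
- **Adsorption rate constant**: k = −slope(ln P vs t)/C in ml/cells/min
  from an unadsorbed-phage decay series sampled in minutes at fixed cell
  density C, i.e. the mass-action model P(t) = P₀e^(−kCt).
- **Infection ratio**: infected/total density at a time point, by
  nearest-sample lookup with tolerance half the sampling interval.

## The weighted mutation-accumulation calculus

Whole-population resequencing scores each candidate site per population as
absent (weight 0), polymorphic (0.5) or fixed (1). Accumulation along a
lineage is Σ|Δweight| per site per sequenced interval. This single rule
covers appearance (0→1 counts 1), partial sweeps (0→0.5 counts 0.5) and
reversions (1→0.5→0 counts 0.5 twice): a site that rises and falls did
twice traverse the population.

An ancestral population may itself be polymorphic at a site (the packaged
dataset has one such site, heterogeneous G/A in the founding stock even
though it derives from cloned cDNA). Such sites start at weight 0.5, so
their later fixation adds only 0.5 in the first interval; each such case is
logged.

**Fixation rate** is count/(L·G) with L the genome length and G the
lineage's final generation number; group summaries report the mean ±
sample SD of per-line rates, and the acceleration `ratio` is
mean(A)/mean(B). Note one convention subtlety: with two lines per group,
the mean-over-mean ratio of the packaged dataset is 3.3, while the
published headline factor (3.4) corresponds to the representative
copropagation line (the one whose 7.5-mutation count is quoted) over the
phage-only group mean. Both are computable from the returned per-line
rates; the tests document both.

**Gene-level bias**: the weighted count inside a gene (k) against the total
(n) is compared with the gene's length fraction p0 by an exact two-tailed
binomial test (minimum-likelihood second tail). Two tallies are available:
`cumulative` (default) sums each line's Σ|Δweight| increments — the same
counting that builds the accumulation curves — and `final` uses only each
line's final population weights. The published 65.5% A2 share corresponds
to the cumulative tally over the two copropagation lines (9.5 of 14.5
weighted mutations); the final-population tally gives a smaller share, so
the tally in use is always recorded on the result. Weighted counts are
half-integers; they are doubled (9.5/14.5 → 19/29) to permit the exact
test while preserving the observed fraction (rounding is available behind
a flag). p0 uses the annotation-derived CDS fraction (1263/4217 = 0.2995
for A2) rather than a rounded 30%.

**Codon annotation** translates the affected codon against the reference:
gene position = genome position − gene start + 1, codon index
⌈gene position/3⌉. Overlapping genes (the read-through A1 shares the coat
start) each yield a record. One special case: an AUG→GUG substitution in a
gene's first codon is classed synonymous, since non-AUG start codons still
initiate with (formyl-)Met.

**Poisson rate comparison**: P(X ≥ observed) under λ = reference rate ×
L × G, for asking whether an observed count is excessive relative to a
mutation-accumulation rate measured elsewhere.

**Bottleneck Ne**: initial phage count × infecting fraction, the standard
per-passage bottleneck proxy. (In the source experiment's own numbers, 1%
of 10⁶ gives 10⁴, although ~10³ is quoted alongside; the operation simply
returns the product.)

## Statistical battery

ANOVA is the classical between/within decomposition. Post hoc pairwise
comparisons use the studentized-range statistic; with unequal group sizes
the Tukey–Kramer per-pair harmonic standard error is applied automatically,
and the variant used is reported. The slope-comparison ("ANCOVA") test
fits y ~ group × x on log-scale data and tests the interaction by a nested
model comparison (df k−1, N−2k); pairwise slope contrasts use the pooled
residual variance with a studentized-range adjustment. Welch's t uses
Satterthwaite degrees of freedom. The slope t test is
(b₁−b₂)/√(SE₁²+SE₂²) with df n₁+n₂−4. Degenerate inputs have defined
conventions rather than NaNs: zero within-group variance with equal means
gives F = 0 (p = 1), two zero-variance samples with equal means give t = 0
(p = 1).

Distributions and the linear-model machinery come from scipy and
statsmodels; the exact binomial is scipy's `binomtest` (the
minimum-likelihood convention). The test suite checks every test against
an independent route: full enumeration for the binomial (≤ 50 trials, to
1e-12), `scipy.stats.tukey_hsd` for the range tests, nested-model
statsmodels ANOVA for the interaction F, closed-form hand computations for
Welch, and 1,000-replicate null simulations for type-I error (±2 SE band).
Discrete tests (exact binomial) cannot sit exactly at nominal α and are
calibrated by enumeration instead.

## The mechanistic coculture simulator

State per ml: susceptible cells S, staged infected cells E₁..E_n, free
phage P.

    dS/dt  = μ S (1 − (S+I)/K) − k_h S P
    dE₁/dt = k_h S P − δ E₁
    dEᵢ/dt = δ (E_{i−1} − E_i)
    dP/dt  = b δ E_n − k_h S P

with I = ΣEᵢ. The latent period τ is realized as an n = 5 stage Erlang
chain (δ = n/τ per stage), which reproduces the observed lag between
infection and free-phage rise without a delay-differential solver.

Defaults (each a `PhageHostParams` field):

| parameter | default | unit | basis |
| --- | --- | --- | --- |
| μ | 0.382 | 1/h | ancestral-host growth rate (evolved hosts ≈ 0.466) |
| K | 3×10⁸ | cells/ml | glucose-limited plateau (OD ≈ 0.4) |
| OD per cell | 0.4/3×10⁸ | OD·ml | plateau conversion; a parameter, since the OD/CFU ratio drifts over long experiments |
| k_ads | 1.4×10⁻⁹ | ml/cells/min | measured adsorption constant; stored in assay units, converted ×60 internally (centralized, tested) |
| τ | 1.0 | h | ≈1 h burst time of the phage |
| n_latent | 5 | stages | Erlang shape |
| b | 413.8 | phage/cell | tuned by bisection (below) |
| resistance factor | 1.0 | — | multiplies k_ads for partially resistant hosts |

Resistance is modelled as a reduced adsorption constant, not absorption
immunity — the mechanism indicated by adsorption assays on evolved hosts.
Stationary-phase refractoriness is a **within-day latch**: once S+I reaches
95% of K the adsorption term is switched off for the remainder of that
culture day. Glucose exhaustion in batch is irreversible, and a reversible
threshold gate would re-open as soon as lysis pulls the culture below the
plateau, letting the phage chain-react all day.

**Burst size** is the one free parameter without a printed value; it is set
by a bisection oracle (`tune_burst_size`) so the phage-only reference
scenario (μ = 0.46, K = 3×10⁸, k = 1.4×10⁻⁹ ml/cells/min, MOI 0.5, 6 h)
amplifies ~1,000-fold, the amplification observed in that regime. The
tuned default is 413.8; the fold response is steep in b at this operating
point, so the consistency check asserts a factor-of-3 band.

**Integration.** Deterministic mode is fixed-step RK4 on a 0.01 h grid.
The adsorption term turns stiff at high phage density (k_h·P can exceed
10²/h), where a naive fixed step goes unstable and the non-negativity clip
would inject mass; each output step is therefore subdivided adaptively in
proportion to the local rate scale (capped at 10⁴ substeps). Linear
conservation laws (P + bT − S constant when μ = 0) then hold to relative
1e-6, and phage-free cultures match the logistic closed form to 1e-6.
Stochastic mode is a seeded tau-leap of the same rates on particle counts
in the culture volume, with Poisson event counts clamped to available
reactants; its seed fully determines a run. The tau-leap mean carries an
O(dt) bias relative to RK4, so the deterministic-limit test uses a
small-population scenario where demographic noise dominates that bias.

**Serial passages** chain days: day d+1 starts from day d's final state
divided by that day's dilution factor (to a target OD, or a fixed factor);
the phage-only regime replaces the host with fresh ancestral cells daily
and re-seeds phage at the protocol titre. Extinction (either population
below one particle per culture volume) is an event, not an error.

**The coexistence scenario** (`coexistence_scenario`) uses strong partial
resistance (3×10⁻⁴, the order implied by sub-0.1% infection ratios) and a
burst size of 50, giving a daily free-phage amplification of ≈6–7× against
the ≈8× daily dilution — inside the 2–20× per-day range observed in
copropagation. A fixed-parameter deterministic system of this form is
intrinsically near a knife-edge: persistent amplification above the
dilution factor drives phage densities to host-extinguishing levels, below
it the phage slowly washes out. The scenario sustains both populations
through 50+ passages (the property the experiments showed over 54 days);
its longer-horizon drift is real and documented, because in the living
system continued coexistence was maintained by ongoing coevolution —
reciprocal parameter change — which a fixed-parameter simulation
deliberately does not include. The "increased burst frequency"
interpretation of phage counter-adaptation is likewise only encoded as a
tunable lysis rate, not asserted.

## The substitution-process generator

Sites arise as Poisson events at rate r per base per generation, with
per-gene relative multipliers (e.g. an A2-enriched process) weighting both
the arrival rate and the placement of sites. A new site is polymorphic for
`polymorphic_dwell` generations, then fixes, or reverts to absent with
probability `reversion_prob`. Statuses are sampled at requested
generations; sites absent at every sampled generation are dropped, as
resequencing would never see them. With dwell 0 and no reversion the
sampled count is Poisson(r·L·G), which anchors the estimator-recovery
tests; with multipliers m the in-gene fraction converges to
m·f/(m·f + 1 − f) for a gene occupying fraction f of the genome.

## Packaged data and the synthetic reference

The packaged status matrix transcribes the published 14-site × 9-population
resequencing table of the Qβ coevolution experiment (two copropagation
lines over 163/165 generations; two phage-only lines over 169/168), with
population generation stamps and lineage membership in its header. The
A2 CDS (61–1323) and the shared coat/A1 start (1344) are fixed by the
published genome-position/gene-position offsets; the remaining gene ends
follow the canonical Qβ gene order and protein lengths. The reference
FASTA is **synthetic**: 4,217 nt in which every published codon context is
embedded at its printed coordinates and all other coding positions are
random non-stop codons. It supports coordinate math and codon annotation
of the tabulated sites exactly, but it is not the deposited genome
sequence and must not be used as one.

## What passing tests do and do not show

The simulator emulates logistic growth, mass-action adsorption, Erlang
latency, burst release, daily dilution regimes and site-status mutation
trajectories with known ground truth — enough to exercise every estimator
end to end and to verify parameter recovery. It does not model
intracellular replication, sequence-level evolution (only site statuses),
spatial structure, phage decay, host physiological heterogeneity, or
coevolving parameters; agreement of estimators with this generator
therefore validates the calculus, not the biology of any particular real
dataset. The fitness tables of the source experiment cannot be recomputed
here because their raw OD/PFU readings are not published; the fitness
operations are instead pinned by inversion unit tests (a printed fitness
value back-calculates to its defining ratio), and the printed F statistics
imply data layouts (replicates entered individually vs averaged) that are
documented but not reverse-engineered.
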
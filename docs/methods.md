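# Methods

This note documents the models implemented in physofrac, the synthetic
cohort generator's assumptions, the numerical choices, and the limits of
what passing tests demonstrate.

## Sorting-depth capture model

Sorting N events from a community where a taxon has prevalence p yields
X ~ Binomial(N, p) captured cells. The tail is computed as
P(X ≥ k) = `scipy.stats.binom.sf(k-1, N, p)` (regularized incomplete beta),
which is stable for N in the 10^5 range where direct pmf summation is not.
The convention throughout is "capture **at least** k"; the complementary
"k or fewer" phrasing is 1 minus this. `min_events` inverts the model by
doubling then bisection, exact because the tail is nondecreasing in N. An
optional purity adjustment replaces p with p(1 − gate_error), off by
default.

## Preprocessing rules

Filters run in a fixed order — sheath decontamination, phylum-unassigned
removal, prevalence filter, named contaminants — and every rule emits a
report whose removed-read totals reconcile exactly with the table before and
after.

* **Sheath decontamination.** An ASV is a contaminant iff it has ≥ 1 read in
  any sheath control and 0 reads in *every* unsorted (Whole) sample, pooled
  across individuals. Sheath controls are then dropped. The rule is
  idempotent and, on generator output (where contaminants are constructed to
  be absent from Whole samples), achieves precision = recall = 1.
* **Prevalence filter.** "≥ 6 reads in ≥ 2 samples" is interpreted
  per-sample: an ASV is kept iff at least 2 samples each contain at least 6
  reads (the common phyloseq filtering idiom), not a summed-total reading.
  This interpretation is a documented choice; both thresholds are
  parameters.
* **Variance-stabilizing transform.** A regularized-log shrinkage transform
  is replaced by the simpler median-of-ratios construction: size factor
  s_j = median over ASVs with nonzero geometric mean of count_ij/geomean_i,
  transformed value log2(count_ij/s_j + 1). The two agree in what matters
  here — depth normalization plus log-scale variance stabilization — without
  a fitted prior. When no ASV is present in all samples, s_j falls back to
  library size over mean library size (logged).
* **Rarefaction** is exact sampling without replacement via the
  multivariate hypergeometric distribution, used only for alpha diversity;
  beta diversity uses relative abundances of filtered counts.

## Beta diversity and ordination

UniFrac is computed from per-branch descendant masses obtained in one
postorder accumulation over a flattened tree index; weighted UniFrac is
Σ l_b|p_A − p_B| (default raw, `normalized=True` divides by Σ l_b(p_A+p_B)),
unweighted UniFrac the unique/total branch-length ratio. Distances consume
**relative abundances of the filtered counts**, not VST values: branch
masses require non-negative proportions, whereas log-transformed values can
be negative. The VST matrix is still produced for reporting. PCoA is the
classical Gower double-centering −½ J D² J followed by `eigh`; coordinates
use positive eigenvalues only, negative eigenvalues are reported without
Cailliez/Lingoes correction. Shannon entropy uses natural logarithms.

## PERMANOVA

The distance-based linear model: G = −½ J D² J, sequential (Type I) sums of
squares by projecting G onto the orthonormal column spaces of the growing
design matrix (intercept, then each dummy-coded term), pseudo-F per term
against the residual, p by freely permuting sample labels with
p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is never zero. For ≤ 8 samples an
exact mode enumerates all n! permutations. The nested design `inner %in%
outer` enters the outer main effect first and then the outer×inner
combination factor; degrees of freedom come from column-space ranks, so
redundant dummies and empty cells are handled without special cases.

Treatment-experiment summaries additionally fit three *single-term* models —
physiology; treatment; treatment-within-physiology — each alone, mirroring
the convention of reporting one R² per model (their sum may exceed 1; the
sequential decomposition is also reported).

## Beta-binomial differential abundance and dispersion

Counts y of one taxon out of totals n follow BetaBinomial(n, α, β) with
α = μ(1−φ)/φ and β = (1−μ)(1−φ)/φ; μ is the mean relative abundance, φ the
within-group overdispersion (φ → 0 recovers the binomial). Fits maximize the
likelihood over unconstrained logit(μ), logit(φ) with L-BFGS-B,
method-of-moments starts, and warm starts of each richer model from the
null fit (which also enforces the likelihood ordering). Differential
abundance is the LRT of group-specific μ against shared μ at shared φ
(χ², groups − 1 df); differential dispersion the LRT of group-specific φ
against shared φ at group-specific μ. Wald machinery is not implemented —
LRTs are asymptotically equivalent and simpler. All-zero (or all-saturated)
taxa return a flagged non-converged row rather than an error. Simulated
calibration at 20 samples/group, 50 trials, φ = 0.1: type-I error of the
abundance LRT ≈ 0.059 over 1,000 null taxa, and recovered group means are
within 0.05 of truth on average at that design size (a single 20-sample fit
has sampling SE ≈ 0.037, so per-fit deviations above 0.05 are expected).

Rank statistics (Kruskal–Wallis with tie correction, Pearson) are delegated
to scipy; Dunn's post hoc z-statistics with the pooled tie term are
implemented here and Benjamini–Hochberg adjusted. Vs-control comparisons use
Welch t-tests (n = 3 replicates with visibly unequal spreads make the pooled
variance assumption inappropriate).

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions the analyses assume.

**Fraction proportions.** Per individual, (HNA, BONCAT+, PI+) percentages
come from a Gaussian copula with truncated-normal marginals on [0, 100]
(defaults 51.73 ± 17.59, 49.01 ± 18.54, 15.73 ± 14.58) and correlations
r(HNA, PI+) = 0.74, r(HNA, BONCAT+) = −0.62, with the unreported third pair
completed as their product (−0.459), the conditional-independence completion
that keeps the matrix positive semi-definite. LNA = 100 − HNA. Truncation is
applied by inverse CDF, and the latent marginal parameters are solved
(2-D root finding on the truncated-normal moment equations) so that the
*realized* mean and SD equal the configured ones; latent pairwise
correlations are likewise solved by monotone root finding with 2-D
Gauss–Hermite quadrature so the realized Pearson correlations equal the
configured ones. Naive truncation (rejection or clipping) was rejected
because the PI+ marginal places ~14% of its untruncated mass below zero,
which would bias the realized HNA mean by ≈ +3 points and shrink
r(HNA, PI+) to ≈ 0.66 — the generator would not reproduce its own configured
moments. With sd = 0 a marginal degenerates to its mean exactly.

**Community structure.** Each cohort draws a rooted binary pure-birth tree
with monophyletic phyla (default mix 61/30/5/4% Firmicutes/Bacteroidetes/
Actinobacteria/Proteobacteria); phylum stem branches are long (0.75 + noise)
relative to within-phylum branches (mean 0.1), as in 16S phylogenies where
phyla are deeply separated. Presence follows the configured prevalence
structure exactly: 12 ASVs in all 10 individuals, 20 more in 8–9 (32 "core"
at the relaxed 8/10 threshold), 477 in exactly one, the rest in 2–7.
Log-abundances are taxon effect + individual deviation; core taxa get a
+2.5 log-unit abundance bonus and a 4× smaller individual-level SD — an
occupancy–abundance relationship: taxa found in everyone are consistently
abundant. This is what makes the active fraction's similarity structure
reproducible (below).

**Propensities and calibration.** Taxon t enters fraction f with probability
θ_tf = logistic(logit(base_f) + phylum offset + core/unique offset + noise),
shared across individuals. Defaults: HNA base 0.25 with +2.0 Firmicutes /
−2.0 Actinobacteria offsets, +2.5 for core and −2.5 for unique taxa, noise
SD 0.6; PI+ mirrors HNA's phylum skew at lower strength; BONCAT is
taxonomically neutral (the study's point: activity is not strongly
taxonomically structured). These values are not measured quantities; they
were set once so the generator reproduces the qualitative contrasts the
analyses are meant to detect (HNA Firmicutes-enriched relative to Whole,
HNA core-enriched/unique-depleted, HNA most similar across individuals) at
approximately the printed magnitudes, and they stay fixed.

Individual-level gate percentages are matched exactly by calibrating
aggregate membership Σ_t a_t·θ'_tf to π_if/100 (residual ≤ 1e−8, monotone
root finding). Two calibrations are provided:

* `scale` (default): θ' = min(1, c·θ). Below the cap this preserves the
  *relative* composition of the in-gate pool, so how active an individual is
  does not reshape which community its active fraction contains.
* `logit`: θ' = logistic(logit(θ) + δ), a uniform odds shift. This couples
  fraction composition to π_if through the logistic nonlinearity: across a
  cohort whose gate percentages vary with SD ≈ 18 points, between-individual
  HNA distances then track |Δπ| (r ≈ 0.6) and swamp the core-similarity
  signal. It remains available for sensitivity analyses.

**Sorting and sequencing.** Each of the 5 gates (HNA, LNA = complement,
BONCAT±, PI+) sorts 180,000 events per individual: in-gate with probability
1 − gate_error (drawn from a_t·θ'_t normalized), leaked otherwise (from the
complement distribution). Default gate errors: BONCAT+ 0.20, BONCAT− 0.057
(matching re-acquired purities of 80% and 94.3%), 0.05 for the
SYBR/PI gates, whose purities are known only to be higher. Libraries are
multinomial at 30,000 reads; sorted samples are spiked with 341–2,333
contaminant reads (uniform total, split over 2 Pseudomonas-like ASVs absent
from Whole samples); one sheath-only control is emitted per individual (one
simulated sorting day each). Cytometry tallies are binomial draws at 100,000
analyzed events per stain, with HNA + LNA complementing exactly within the
SYBR acquisition.

**Treatments.** Each configured individual × treatment × replicate draws
fresh fraction proportions around the treatment means (moment-matched
truncated normals; defaults encode the glucose/digoxin/nizatidine shifts,
e.g. BONCAT+ 28 ± 17 → 60 ± 7.9 for individual 1 and 27 ± 7.5 → 67 ± 3.5 for
individual 2, with HNA and PI+ shifts for individual 1 and no HNA/PI+
response for individual 2), recalibrates, and reruns sorting and sequencing.
Treatment draws are independent across fractions (within-incubation
correlations of the responses are not modeled).

**What the generator does not model.** 16S copy-number variation (reads are
proportional to cell tallies), PCR/chimera error, fluorescence intensities
or FCS event data, compositional correlations between treatment responses,
and real taxonomies. Tests passing on this generator show the pipeline's
rules and statistics behave correctly under the assumed mechanism — shared
propensities, individual-specific communities, binomial/multinomial
sampling — not that real sorted communities satisfy those assumptions.

## Problem sizes, determinism, degenerate inputs

Everything is seeded: one integer seed drives tree, structure, copula,
propensities, sorting, sequencing and cytometry through spawned seed
sequences, and identical configuration + seed gives byte-identical outputs.
Unit tests run on reduced cohorts (80 taxa, 20,000 events, 3,000 reads;
effect settings unchanged) so the suite stays fast; full-scale defaults
(838 taxa, 180,000 events) are exercised by the structure/acceptance checks,
which use 10 independent seeds for each qualitative ordering and 999 or
fewer permutations where only effect sizes are compared. Statistical power
caveat: with n = 3 replicates, the glucose/BONCAT+ contrast is reliably
detectable for the individual-2 parameterization (control SD 7.5) but not
the individual-1 one (control SD 17, Welch p ≈ 0.065 at the true means), so
the power assertion targets the former.

Degenerate inputs have defined behavior: zero-variance marginals give
constants; all-identical values give H = 0, p = 1 (Kruskal–Wallis) or p = 1
(vs-control with equal constant groups); all-zero taxa give flagged NA test
rows; empty in-gate mass raises a degenerate-fraction error; samples below
the rarefaction depth are dropped with a warning; percentages print at one
decimal using round-half-even (349/838 prints as 41.6%; arithmetic that
rounds half-up would print 41.5%).
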
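# Methods

This note documents the models, estimators, numerical choices and known
limitations of `milletpop`, stage by stage.

## Input conventions and filtering

Coordinates are 1-based inclusive everywhere in memory (VCF/GFF native);
BED export subtracts 1 from starts. Genotypes are coded 0/1/2 copies of a
designated allele with a −1 sentinel for missing; half calls (`./1`) are
missing. A variant is an SV when either allele exceeds 50 bp, else a SNP.

Site filtering follows VCFtools semantics, where `--max-missing` is —
despite its name — a *keep* threshold on call rate. The two standard
filter sets are exposed as constants: SNPs (call rate ≥ 0.8, GQ ≥ 10,
MAF ≥ 0.05) and SVs (call rate ≥ 0.7, GQ ≥ 20, MAF ≥ 0.01). MAF is
computed on called alleles after GQ masking, so the missingness and
frequency criteria see the same call set; with that convention the two
filters commute. One practical consequence, visible in the pipeline: a
MAF filter strips rare derived alleles, which include most deleterious
sites in a purged cohort, and removes the invariant site classes the CLR
scan uses — so the burden and CLR stages run on unfiltered (polarized)
data while windowed F<sub>ST</sub>/PBS runs on the filtered set.

## The synthetic cohort generator

A discrete-generation Wright–Fisher model on unlinked sites. Per
generation and site: deterministic selection against the derived allele
(fitnesses 1, 1−hs, 1−s for 0/1/2 derived copies), one-way mutation influx
q ← q + μ(1−q), then binomial resampling of 2N gametes. Demography:
ancestral population of size N_wild; the outgroup branches `outgroup_gen`
generations before present; the cultivated population splits from the wild
lineage `split_gen` generations ago with bottleneck size N_cult.

**Initialization.** There are no published demographic parameters for
foxtail millet domestication, so the generator's defaults are desk-scale
placeholders chosen to reproduce the qualitative regime the analyses
assume: standing ancestral variation is drawn from a neutral
site-frequency spectrum (density ∝ 1/q, i.e. log-uniform on
[1/2N, 0.95]), followed by a 200-generation selective equilibration so
deleterious sites relax toward mutation–selection balance. Defaults
(N_wild = 500, N_cult = 100, split 60, outgroup 300 generations) keep
per-branch drift moderate (F ≈ 0.1–0.3): the wild population retains
diversity, the cultivated population loses a visible fraction of it, and
the outgroup is substantially but not completely sorted. A `monomorphic`
initialization (all sites at frequency 0, variation supplied by mutation
alone) is available for analytic checks. Per-site mutation rates
(10⁻⁵/generation) are orders of magnitude above per-bp reality — the
simulated sites stand in for the informative fraction of a genome, not
for contiguous sequence.

**Sweeps.** A beneficial allele (semidominant, coefficient s_b) starts at
one copy in the cultivated population at the split; its trajectory is
re-drawn until it reaches frequency ≥ 0.95 (rejection sampling conditioned
on near-fixation), with a deterministic logistic trajectory as the capped
fallback. Linkage is emulated at sampling time with the same escape model
the CLR scan assumes: at a site at distance d from the sweep, each sampled
cultivated haplotype escapes with probability 1 − e^(−αd); a non-escaping
haplotype carries the hitchhiker's allele (one Bernoulli draw per site at
the sweep-onset frequency), an escaping haplotype samples the present-day
drifted frequency like the rest of the genome. The footprint scale α
defaults to 2 × 10⁻⁵ per bp (half-escape distance ≈ 35 kb); the demo
configuration widens it to 5 × 10⁻⁶ (≈ 140 kb), the scale of strong
domestication sweeps, which is what lets the full pipeline — with
polarization error — localize the sweep reliably.

**Ancestral labelling and SIFT scores.** The derived allele is ALT at half
the sites and REF at the other half, so the polarization stage does real
work. SIFT-like scores are synthetic labels — Uniform(0, 0.05) at
deleterious sites, Uniform(0.05, 1) elsewhere — not sequence-derived;
score computation is upstream of this package.

**Phenotypes.** y_t = Σ_j β_tj x_j + e_t on mean-imputed, standardized
dosages; a shared causal set with effects drawn from a multivariate
normal across traits induces the requested genetic-correlation matrix
(validated positive semidefinite before simulation), and genetic values
are rescaled so each trait's variance fraction meets its target h².
Realized h² and realized genetic correlations are reported in the truth
record; in small or strongly related panels the realized r_g fluctuates
around its target because the causal-effect quadratic forms have few
effective degrees of freedom.

**Related panel.** `simulate_related_panel` draws each individual's two
haplotypes from a small founder pool, emulating the shared ancestry of a
crop accession panel. Variance-component estimation (h², r_g) relies on
off-diagonal kinship variance, which unrelated i.i.d. genotypes do not
provide at desk scale; the recovery experiments therefore use this panel.

**What the generator does not emulate:** recombination maps and true
linkage (sites are unlinked apart from the sweep transformation), gene
conversion, sequencing error beyond a uniform missingness/GQ mechanism,
population admixture, and multiallelic variation. Passing tests
demonstrate internal consistency of the estimators under the stated
model, not robustness to these real-data features.

## Pangenome

Occupancy bands generalize the 26-genome convention to N genomes:
core = N, soft-core = N−2..N−1, dispensable = 2..N−3, private = 1;
families present nowhere are rejected. Pan/core curves are cumulative
union/intersection counts over seeded random permutations of genome
order; monotonicity holds per permutation, and the k = N endpoints are
permutation-free. The gain/loss rule defaults to strict absence — gained
families occur in ≥ 1 cultivated genome and no wild genome (mirror for
lost) — because strict absence is the reading consistent with calling a
family gained or lost *during domestication*; a `min_frac` knob tightens
the own-clade presence requirement.

## Burden

Ancestral alleles are inferred from the outgroup: the allele at frequency
≥ 1 − tol among called outgroup alleles (default tol = 0, i.e. fixed);
sites with too few outgroup calls or a polymorphic outgroup stay
unpolarized and are excluded from burden work. A variant is deleterious
iff its SIFT score is strictly below 0.05 (configurable), the site is
polarized, and the derived allele is the substituting (ALT) allele —
when REF is derived, the recorded score describes the wrong substitution.
Dominance models count, per individual over derived-coded genotypes:
heterozygous = n_het, homozygous = n_hom(derived), additive =
n_het + 2·n_hom. Burdens are reported raw and per called site, because
groups differ in missingness. Group comparison: reduction% =
100·(mean_wild − mean_cult)/mean_wild, a seeded bootstrap CI over
samples, and a two-sided Wilcoxon rank-sum test; a zero wild mean makes
the reduction undefined and is reported as such. SV burden defaults to
all polarized SVs, with a genic-SV option (SVs in gene bodies).

A modelling observation worth recording: under the bottleneck-with-
recessive-deleterious regime, the *additive* burden (mean derived
frequency) is consistently lower in the cultivated population — purging —
while the *homozygous-model* burden has no consistent direction at desk
scale, because drift-driven homozygosity in the bottleneck offsets the
purging of recessives. The direction tests therefore assert the additive
model.

## Selection scans

Hudson's F<sub>ST</sub> estimator is used throughout: per site
N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), D = p₁(1−p₂)+p₂(1−p₁);
a window's value is ΣN/ΣD (ratio of averages, robust to unequal sample
sizes), with per-site components exposed for oracle testing and sites
lacking two called alleles in either group excluded. Windows contain a
fixed number of SNPs (default 100) with a start-index step (default 101 —
the literal upstream convention, which skips one SNP between consecutive
non-overlapping windows); trailing partial windows are dropped.

PBS for the cultivated branch is (T_cw + T_co − T_wo)/2 with
T = −log(1−F<sub>ST</sub>), F<sub>ST</sub> clamped into [0, 1−10⁻⁶]
before the log; the identity PBS_c + PBS_w = T_cw holds exactly and is
asserted. Window significance uses the add-one right-tail rank
p = (1 + #{other windows ≥ this one})/(n_windows + 1), which makes a
unique maximum among 99 windows p = 1/100 and puts exactly 5% of windows
at the p ≤ 0.05 band for distinct values; a label-permutation null is
available as an alternative. Both the p ≤ 0.05 set and the smallest-10%
set are returned.

The CLR scan implements the SweepFinder-family hitchhiking model on the
full frequency spectrum (classes 0..n included, with a 0.5 pseudocount):
conditional on a pre-sweep derived count j drawn from the genome-wide
background, each of n sampled lineages escapes a sweep at distance d with
probability p_e = 1 − e^(−αd); the hitchhiking lineage is derived with
probability j/n, non-escaping lineages copy it, escaping lineages sample
Binomial(j/n). Including the invariant classes is essential: the dearth
of polymorphism around a sweep — sites driven to fixation or loss — is
most of its footprint. The likelihood-ratio is clamped at zero,
CLR = 2·max(0, sup_α Λ(α)), which embeds the background model as the null
boundary of the family; on data whose empirical spectrum equals the
background with no spatial structure, Gibbs' inequality makes the clamped
CLR exactly zero. α is maximized by grid search over 50 log-spaced values
adapted to the chromosome span; a constant sample size is enforced by
seeded hypergeometric subsampling of each site's derived count to the
10th percentile of per-site call counts. Fidelity to SWeeD's exact
numerics is not claimed; correctness is established against an exhaustive
escape-configuration enumeration at small n and sweep-recovery
experiments. Known sensitivity: ancestral-allele misassignment (a few
percent with a small, diverged outgroup) dilutes the signal appreciably,
because flipped sites inflate the high-frequency-derived background; with
true ancestral states the scan localizes simulated sweeps to within one
grid point.

Candidate regions come from the top 10% of grid points (or a CLR cutoff),
with adjacent selected points merged; genes are candidates of a scan on
≥ 1 bp overlap with a selected region, on 1-based inclusive intervals.

## Mixed models

The kinship matrix is the standardized (GEMMA `-gk 2`) form; missing
genotypes are mean-imputed per site and monomorphic sites skipped. PCA
operates on the centered (optionally standardized) dosage matrix via SVD,
with each component's sign fixed by its largest-magnitude loading.

The LMM y = Wα + xβ + u + ε, u ~ N(0, σ_g²K), ε ~ N(0, σ_e²I) is fitted
exactly by rotating into K's eigenbasis, reducing REML/ML to a 1-D
optimization over λ = σ_g²/σ_e²: an 80-point grid scan over
log λ ∈ [−11.5, 11.5] followed by bounded Brent refinement (the grid scan
guards against the multimodal restricted likelihoods that single-start
Brent can mishandle). Per variant, the Wald test re-optimizes λ by REML
(F(1, n−c) reference); the LRT compares ML fits (χ²₁); the score test is
evaluated at the null REML fit. With K = I the Wald p reduces to the OLS
t-test p exactly. The rotated restricted likelihood equals the dense
multivariate-normal evaluation on error contrasts to machine precision
(asserted at 10⁻⁸ relative). h² is reported on the K-as-given scale as
λ̂/(1+λ̂), with a delta-method standard error from the numerical curvature
in log λ; boundary estimates are flagged. Significance thresholds: the
study's Bonferroni rule 0.05/n and the fixed genome-wide 10⁻⁸.

Bivariate REML stacks the two traits per eigencomponent —
y_i ~ N(X_i α, d_i V_g + V_e) with 2×2 genetic and residual covariance
matrices — and maximizes the restricted likelihood by L-BFGS-B under a
log-Cholesky parameterization (positive-definiteness by construction),
initialized from the Haseman–Elston cross-product regression, which is
also reported as an independent method-of-moments cross-check.
r_g = σ_g12/√(σ_g1²σ_g2²), clamped to [−1, 1] with a flag; identical
traits recover r_g = 1 to within the parameterization's interior
tolerance (~10⁻³).

## Annotation layer

Candidate regions are significant variants flanked by ±50 kb (a common
LD-informed convention; configurable and logged) with overlapping windows
merged per trait — merging is idempotent — and the lead variant is the
clump's smallest p. Overlap counts (deleterious variants in regions, in
candidate gene bodies, SVs in candidate genes) are reported per trait and
per chromosome, with trait-pooled totals; all interval logic is exactly
reproduced by quadratic brute-force oracles in the tests.

## Pipeline, seeds, problem sizes

The `pipeline` command expands one global seed into per-stage seeds with
`SeedSequence(seed, spawn_key=(stage_index,))`, so stages can be rerun
independently; a manifest records a SHA-256 checksum per output, and
reruns are bit-identical. The shipped demo (3,000 sites, 195 accessions)
runs in well under a minute; the test suite's recovery experiments use
20 replicates at n = 500/m = 2,000 (h²), n = 400/m = 1,000 (r_g) and
3,000-site single-chromosome cohorts (sweep localization, with
missingness disabled and true ancestral states so the experiment measures
the scan rather than the polarization stage). These sizes were chosen as
the smallest at which the estimators' sampling noise is clearly below the
effects being recovered.

## Limitations

- Unlinked sites: no LD beyond the sweep transformation, so LD-based
  clumping and haplotype statistics are out of scope.
- The CLR model is the single-hitchhiker escape approximation with a
  constant sample size; recombination-rate-aware scanning is not
  implemented.
- Polarization against a small diverged outgroup misassigns a few percent
  of sites; downstream burden comparisons are robust to this (errors hit
  both groups symmetrically) but sweep-scan power is not.
- The paper-scale headline counts (millions of SNPs, hundreds of
  accessions) are cohort-bound; this package demonstrates the methods'
  correctness and calibration at desk scale rather than reproducing those
  numbers.
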
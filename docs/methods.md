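# Methods

## The problem

Large GWAS meta-analyses of polygenic traits show inflated association
statistics. Two corrections are in routine use:

* **Genomic control (GC)** divides every 1-df association χ² by the
  inflation factor λ = median(observed χ²) / median(χ²₁), where the χ²₁
  median is ≈ 0.45494 (usually printed 0.454). λ > 1 is read as inflation.
* **LD-score-regression (LDSR) intercept correction** fits
  E[χ²ⱼ] = intercept + (N·h²/M)·ℓⱼ, where ℓⱼ = Σₖ r²ⱼₖ over variants
  within a window (self term included). The intercept isolates confounding
  (target 1) from polygenicity (the slope term), and divides the χ²
  exactly as λ does in GC.

Both corrections assume that a high χ² median signals bias. In a
well-powered meta-analysis of a polygenic trait the median is raised by
real signal, so dividing by λ (or by an intercept > 1) deflates true
associations near the significance threshold. This package quantifies that
cost: how many associations that *replicate in a larger later study*
("robust associations") and how many independent loci are lost when the
earlier study is corrected.

## Pipeline

For an earlier/later study pair sharing a variant set:

1. **Harmonization** — inner join on (chromosome, position); allele-swapped
   records are aligned by negating the later beta and complementing its
   EAF; allele-set mismatches and multi-allelic positions are dropped with
   tallies. All downstream estimates (λ, intercept) are recomputed on this
   shared set.
2. **Classification** at p ≤ 5×10⁻⁸ (boundary inclusive, compared on the
   −log₁₀ scale): TP (robust) = significant in both with concordant beta
   signs; FP = significant in the earlier only, or in both with discordant
   signs; FN = significant in the later only; TN = neither.
   %robust = 100·TP/(TP+FP); FPR = FP/(FP+TN); TPR = TP/(TP+FN).
3. **Correction** — χ² of the earlier study divided by λ (GC) or by the
   LDSR intercept; p recomputed from χ²; betas/SEs untouched. Division is
   applied only when the divisor exceeds 1 (no deflation correction) unless
   forced, which the un-correct/re-correct round trip requires. The later
   study is never corrected.
4. **LOCO resampling** — per chromosome with ≥ 1 earlier-significant
   variant, the observed confirmation rate TP/(TP+FP) is compared against
   100,000 draws (default) of equally many earlier-significant variants
   sampled without replacement from the other chromosomes. The empirical
   p is the smaller tail, p_chr = min(#{Cₛ ≤ C_obs}, #{Cₛ > C_obs})/N, with
   ties in the lower tail; its maximum is 0.5. Chromosomes are reported
   against the Bonferroni level 0.05/(chromosomes tested). Because only
   each sampled variant's confirmed status enters a draw, the number
   confirmed in a draw of size k is exactly hypergeometric; draws are
   generated from that distribution — provably the same null, at a fraction
   of the cost (verified against exhaustive subset enumeration in the
   tests).
5. **Loci loss** — PLINK-style greedy clumping of the uncorrected earlier
   study (index p ≤ 5×10⁻⁸, secondary p ≤ 5×10⁻⁶, r² ≥ 0.20 with the
   index, ±500 kb window read as a radius; p-ties broken by chromosome then
   position). Clumps containing a study-defined index variant are tagged
   (membership, no proximity fallback). Robust associations lost to a
   correction are filtered — MHC region chr6:28,477,797–33,448,354 (GRCh37,
   1-based inclusive) removed; variants absent from the LD reference
   (single-variant clumps) excluded — and the unique untagged clumps
   holding the remainder are the lost independent loci.
   %lost loci = 100·lost/(lost + loci identified in the smaller study).

## LDSR fit details

χ² values above max(80, 0.001·N) are removed first (the reference
implementation's default cap). The regression is a two-step weighted least
squares: an initial fit with overcounting weights 1/max(ℓ, 1), then a refit
with weights 1/[2·(expected χ²)²·max(ℓ, 1)] — the variance of a scaled χ²₁
response times the overcounting factor — where expected χ² comes from the
initial fit. The initial step is deliberately conservative: using full
variance weights before any fit exists would require an h² guess. The
optional intercept standard error is a delete-a-block jackknife over 200
contiguous blocks (variants sorted by chromosome and position). h² is
reported as slope·M/N. The effective sample size of a case-control study is
Neff = 4/(1/N_cases + 1/N_controls). The polygenicity proxy is the Pearson
correlation between χ² and ℓ; it rises with sample size as polygenic signal
is progressively captured.

The LD-score window is a ±1 Mb physical radius (a stand-in for a 1 cM
genetic window; no genetic map is in scope). With bias adjustment, each
r̂² is replaced by r̂² − (1 − r̂²)/(n_hap − 2), removing the ~1/n_hap
upward sampling bias of squared correlations; the self term (r² = 1) is
unaffected, so an isolated variant has ℓ = 1.

## Synthetic data generator

The generator produces exactly the structure the two estimators assume,
so parameter recovery is a meaningful test.

**Panel.** Haplotypes are binary Markov chains in LD blocks (default 50
variants, ~4 kb spacing, blocks ≥ 1.5 Mb apart so no window bridges them;
blocks and chromosomes independent). Within a block, each variant's joint
frequency with its predecessor is set so their correlation equals the
block's LD strength ρ_b (feasible for any ρ < 1 because variants of a
block share similar frequencies: a per-block MAF is drawn from a
beta(0.8, 0.8) spectrum with floor 0.5% — mirroring common "MAF ≥ 0.5%"
filters — with 5% per-variant jitter). ρ_b is normal around the target rho
(default 0.7, spread 0.15) and capped at 0.92; heterogeneous LD across
blocks is what gives the LD-score distribution its spread, and the cap
keeps extreme-LD blocks' χ² well below the LDSR cap at emulated sample
sizes (see "Scaled-down validity" below). The allele coding of a random
half of the variants is inverted (r² is coding-invariant), and monomorphic
columns — possible at floor MAF with a finite panel — get one flipped
carrier so correlations are defined.

**Summary statistics.** Per variant, z = √vⱼ·uⱼ + √c·εⱼ with
vⱼ = N·h²·ℓⱼ·(causalⱼ/π_causal)/M, χ² = z², beta = z·SE,
SE = 1/√(2f(1−f)N). The confounding intercept c ≥ 1 scales the noise;
uⱼ is the genetic component, *shared between the two studies of a pair*
(study-specific ε, optionally correlated via a sample-overlap knob,
default 0), so the later, larger study confirms the earlier study's true
signals. With π_causal = 1 (default) this is the exact LDSR variance model;
sparse settings concentrate the signal in an effect-size tail, which is
what lets a scenario show genome-wide hits while the χ² median stays near
c. Defaults (M = 20,000 over 10 chromosomes, h² = 0.4, c_earlier = 1.2,
c_later = 1, N_earlier = 50,000, N_later = 200,000) are the calibration
conditions used by the recovery tests.

An optional `maf_power` switch multiplies vⱼ by 2f(1−f) (normalized to
mean 1), emulating the lower power of rare variants; it reproduces the
rise of λ as low-MAF variants are removed. It is **off by default**: in a
binary panel allele frequency bounds attainable r², so the factor
correlates with ℓ and bends E[χ²|ℓ] off the straight line — a deliberate
model violation for studying MAF thresholds, not part of the calibrated
generative model.

**What the generator does not emulate.** Test statistics are independent
across variants given ℓ (the LDSR variance form), so LD partners of a hit
are not themselves elevated: clumps of significant variants are small, and
each lost robust association tends to be its own lost locus — real data
lose several correlated associations per locus. There is no genotype-level
phenotype sampling, no population structure, no imputation-quality
gradient, and rsIDs/alleles are synthetic. Passing tests therefore
establish correctness of the estimators and accounting on the assumed
model, not performance on real cohort artifacts.

**Reference scenario.** The end-to-end runs use M = 100,000 variants on 22
chromosomes, π_causal = 0.2, h² = 0.4, c_earlier = 1.2, c_later = 1, and
effective sample sizes computed from the case/control counts of recent
type-2-diabetes meta-analyses (74,124/824,006 → Neff ≈ 272,026 for the
earlier study; 242,283/1,569,734 → Neff ≈ 839,585 for the later). This
yields λ ≈ 1.7 > intercept > 1, a few thousand genome-wide significant
variants, and a TPR before correction of ≈ 0.3 — the regime under study,
at desk scale. The index-variant proxy ("published loci") is obtained by
clumping the earlier study *after* GC correction by its own λ, since
published locus lists derive from corrected statistics; clumping the
uncorrected study and tagging with its own indices would tag every clump
and make loci loss vacuously zero.

**Scaled-down validity.** At reduced M the per-variant signal N·h²/M must
be held fixed (the scenario scales Neff ∝ M), and per-causal-variant
variance must stay well under the χ² cap: once it approaches ~cap/3 the
cap censors the causal tail, saturating E[χ²|ℓ] and destroying the fit.
In the sparse reference scenario a residue of this artifact remains: the
estimated intercept overshoots the generating c (≈ 1.37 vs 1.2) because
the causal tail brushes the cap. The infinitesimal calibration conditions
recover c accurately; the scenario's qualitative orderings
(λ > intercept > 1; GC loses more than LDSR; LDSR-lost ⊆ GC-lost) are
unaffected. This is a known limitation of desk-scale emulation, not of the
estimators.

## Numerical choices

* All p-value arithmetic runs on the −log₁₀/χ² scale through the normal
  log-CDF and its inverse (`log_ndtr`/`ndtri_exp`), exact far beyond the
  double underflow point (p ≈ 1e-308); round trips are tested to
  −log₁₀ p = 320.
* The χ²₁ median is used at full double precision; sample medians of even
  counts use midpoint interpolation.
* Significance comparisons use −log₁₀ p ≥ threshold − 1e-9, so boundary
  equality counts as significant and float noise cannot flip a call.
* A zero beta on a doubly-significant variant counts as direction-
  *inconsistent* by default (configurable), and is logged.
* Greedy-clump index ties are broken by (chromosome, position) ascending;
  the result is invariant to input row order.
* LOCO ties (Cₛ = C_obs) are counted in the lower tail. One integer seed
  drives an entire run; every stochastic operation accepts an explicit
  seed or generator.

## Known limitations

* The intercept correction inherits GC's "divide only when > 1" policy;
  neither study is ever inflated back.
* The LD-score window is physical (±1 Mb), not genetic.
* Clumping does not model cross-chromosome or conditional (COJO-style)
  independence.
* The LOCO resampler draws variants, not LD blocks, so the null ignores
  within-chromosome correlation of confirmation outcomes — as does the
  procedure it implements.
* Sample overlap between the two studies (which inflates observed
  concordance) defaults to zero and is exposed as a config knob without a
  calibrated default.
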
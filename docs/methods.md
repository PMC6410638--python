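# Methods

This note documents the models, conventions and design choices behind the
package, and what the synthetic data does and does not establish about
behavior on real cohorts.

## Cohort model

A cohort is two clinical groups — endometrioid endometrial carcinoma (EEC)
and its precursor lesion, endometrial intraepithelial neoplasia (EIN) —
with per-sample somatic variant calls from a targeted gene panel, optional
germline calls from matched blood, and optional paired tumor/normal
per-region depth profiles. All frequency analyses count a sample at most
once per gene, however many variants it carries there.

## Tumor mutational burden

A variant qualifies for TMB when it is an SNV, its tumor depth is
*strictly* greater than 150 reads, and its allele fraction is at least
0.03. Both bounds are configurable (`FilterPolicy`); the depth bound is
deliberately exclusive and the VAF bound inclusive, and a flag admits
indels for sensitivity analyses. TMB is the qualifying count divided by the
interrogated footprint in Mb, times a multiplicative extrapolation factor.
The factor defaults to 1.0 — panel-level TMB — because no published
panel-to-exome transformation is specific enough to reimplement; anyone
with a validated calibration can supply it as a single multiplier. The
depth filter is applied to the tumor depth recorded on the variant; no
separate normal-depth criterion is imposed at this stage.

Hypermutation is classified on the total somatic mutation count at a
threshold of 100, the midpoint of the gap between the non-hypermutated
(≤ ~48) and hypermutated (≥ ~141) per-tumor count ranges this threshold is
meant to separate; the comparison is inclusive (count ≥ 100). A sample is
DDR-flagged when it has ≥ 1 somatic variant in the DNA-damage-repair set
{POLE, POLQ, MSH2, MSH6, MLH1, MLH3, PMS1, PMS2}.

Group comparisons use the two-sided Mann–Whitney U test, the standard
nonparametric location test for skewed burden distributions. When both
groups have ≤ 8 observations the p-value is computed by exhaustive
enumeration of all C(n₁+n₂, n₁) rank assignments using |U − n₁n₂/2| as the
two-sided criterion (valid under ties); larger groups use the
tie-corrected normal approximation with continuity correction
(scipy). With `exclude_ddr`, DDR-flagged samples are removed from both
groups before comparison.

## Copy-number calling

The caller is a pure paired tumor/normal depth-ratio method: no
segmentation, no GC correction, no cross-sample normalization. Gene
footprints are tiled into fixed 100 bp regions by default (exon-level
regions can be supplied via the BED-like region table; coordinates are
0-based half-open throughout). Per region, LRR = log₂(tumor/normal) using
mean depths. Regions with normal depth below 20 reads, or zero tumor
depth, are *not evaluable*: they produce NaN rather than infinities and
are excluded from both numerator and denominator of the gene-level rule.

Region classification is strict: amplified iff LRR > 0.35, deleted iff
LRR < −0.5. A positive printed deletion cutoff would classify every
slightly-sub-neutral region as deleted, so the deletion bound is taken as
a negative threshold; −0.5 is the default and the value is configurable
(−0.35, the mirror of the amplification bound, is the natural
alternative). The gene-level call requires one non-neutral class to hold a
strict majority — more than 70% — of the gene's *evaluable* regions;
fractions exactly at the threshold never call, and the majority is
computed over evaluable rather than all regions so that low-coverage
regions cannot silently veto a call.

## Association statistics

Per-gene 2×2 tables (rows EEC/EIN, columns mutated/wild-type) are tested
with the continuity-corrected (Yates) Pearson χ² when all four expected
counts are ≥ 5, otherwise with the two-sided Fisher exact test; a zero
margin forces the Fisher branch. This is the convention of the classic
clinical statistics packages, and it reproduces the printed p-values of
the count tables this package's fixtures rebuild (PTEN 0.008, KDR 0.030,
co-mutation 0.046/0.175). The result always records which test ran.

The two-sided Fisher p is the sum of conditional probabilities of all
tables with the observed margins whose point probability is ≤ the observed
table's. It is computed in exact integer arithmetic — hypergeometric
weights are binomial-coefficient products compared as integers, and the
p-value is the correctly rounded float of the exact rational — so there is
no floating-point tie tolerance to tune and agreement with exhaustive
enumeration is exact by construction. χ² goes through scipy.

The differential screen tests every gene in the prevalence table and
judges significance on raw p-values at α = 0.05 by default, matching the
way such gene lists are conventionally reported; Benjamini–Hochberg
adjustment is available behind `correction="BH"`. Co-mutation declares a
sample co-mutated iff it carries ≥ 1 somatic variant in each gene of the
pair, with shares over group sizes.

## Germline screening

Pathogenicity is consumed from input annotations (ClinVar-style labels,
normalized from common spellings), never predicted: the screen keeps
pathogenic and likely-pathogenic records, assigns `lynch` to findings in
{MLH1, MSH2, MSH6, PMS2} and `non_lynch` otherwise, and applies the
recessive rule — in genes requiring biallelic inactivation (default
{MUTYH}) a heterozygous finding is retained as a carrier state but never
actionable. An optional, off-by-default rule upgrades unannotated
truncating variants to likely-pathogenic. The overall carrier rate counts
patients (not findings) over the whole cohort; the Lynch rate is computed
within the EEC group, where mismatch-repair findings drive clinical
follow-up. A homozygous MLH1 finding is still classed `lynch` even though
biallelic MMR inactivation would suggest a constitutional MMR-deficiency
phenotype; the recessive set is configurable for users who prefer to
handle that case separately.

## Synthetic cohorts

The simulator generates the structure the analysis assumes, with ground
truth attached:

- **Design.** 36 EIN + 79 EEC samples by default, with carcinoma grades
  drawn 40:24:15 (G1:G2:G3) and stages dominated by IA — the cohort
  composition of the study design this package models.
- **Drivers.** Per-gene carrier status is exactly Bernoulli with
  group-specific probabilities; the default map assigns each of the 23
  recurrently mutated panel genes its observed group frequencies (e.g.
  PTEN 51/79 EEC, 13/36 EIN). Exact Bernoulli sampling is what makes the
  prevalence-recovery property (observed frequency within 3 binomial
  standard errors for n ≥ 1000) hold gene by gene.
- **Background and hypermutators.** Per-sample background mutation counts
  are negative binomial: mean 7, dispersion 2 for normal samples (counts
  ~0–48) and mean 185, dispersion 30 for hypermutators (counts ~140–280),
  with a hypermutator fraction of 5/115. Every hypermutator receives a
  guaranteed somatic variant in a DDR gene. Background hits land on panel
  genes outside the prevalence map so they cannot distort configured
  frequencies; non-hypermutator background additionally avoids DDR genes,
  because in this condensed ~40-gene toy panel DDR genes would otherwise
  take a grossly larger share of background hits than they do in a
  full-size panel footprint. Sporadic DDR carriers still arise through the
  POLQ prevalence entry.
- **Depths and VAFs.** Per-variant depths are negative binomial around the
  configured means (tumor 1690×, normal 2389×, dispersion 8); VAFs are
  Beta(mean 0.25, concentration 8) clipped to (0, 1]. Region-depth
  profiles model the *mean* depth of ~100 bp windows and therefore use a
  much tighter dispersion (150); copy-neutral regions are generated with
  equal tumor and normal expectation — i.e. the profiles emulate
  library-size-normalized coverage, which is what a pure ratio caller
  assumes of its input.
- **CNV spike-ins.** Configured as (gene, group, carrier fraction, log2
  fold); the default plants a +1 log₂ VEGFB amplification in 19/79 EEC and
  1/36 EIN samples. `spike_cnv` additionally lets tests scale an arbitrary
  fraction of a gene's regions in an existing profile.
- **Germline.** Pathogenicity labels are assigned directly from a bundled
  template list of ten pathogenic/likely-pathogenic findings (assigned to
  EEC samples at rate 10/79), plus low-rate VUS/benign noise. No
  annotation database is simulated.
- **Panel.** The bundled panel is a synthetic ~40-gene toy (recurrent +
  DDR + germline genes + VEGFB) with plausible coding-footprint sizes,
  0.163 Mb total; the real 363-gene design is not public. TMB values on
  simulated data are therefore on a panel-footprint scale of their own and
  are never compared against clinically reported mutations/Mb.

What passing on synthetic data shows: the pipeline's bookkeeping,
thresholds, test selection and calling rules behave exactly as specified,
and effects planted at realistic sizes are recovered. What it does not
show: robustness to alignment artifacts, FFPE damage, GC-coverage bias,
subclonal copy number, or mis-annotation — none of which the generator
models.

## Determinism and numerics

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical cohorts and reports. Report floats are formatted at 6
significant digits; sort orders are fixed (prevalence by descending count
then gene name, findings by gene then sample). Degenerate inputs are
handled by explicit markers rather than exceptions where a value is
legitimately undefined: zero-variant exon fractions return an undefined
marker, non-evaluable regions return NaN, zero-margin tables return p = 1.

## Problem sizes used in checks

The bundled verification suite enumerates all 135,751 2×2 tables with
N ≤ 40 for the Fisher oracle, uses 100 simulated replicates at 200 samples
per group for the differential screen's power estimate (0.20 vs 0.50
prevalence), and measures CNV spike recovery on the default 115-sample
cohort; these sizes keep every check comfortably within interactive
runtimes while leaving the statistical conclusions unambiguous.

## Known limitations

- The whole-exome extrapolation factor is a plain multiplier; the package
  makes no claim of comparability with any commercial TMB scheme.
- The deletion LRR cutoff is a judgment call (see above); analyses
  sensitive to deletions should sweep it.
- No multiple-testing correction is applied by default — the raw-α
  convention matches how the underlying gene lists are usually reported,
  but screens over many genes should enable BH.
- Per-sample variant-count distributions of the simulator beyond the
  configured medians/ranges are plausible stand-ins, not estimates from
  data.
- MSI status, mutational signatures, purity/ploidy and driver-gene
  significance modeling are out of scope.
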
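# Methods

This note documents the models implemented in `wexscape`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Scope and inputs

The package starts where variant calling ends.  Inputs are a MAF-like
somatic mutation TSV (sample, position, alleles, gene, classification,
alt/ref read counts, optional precomputed trinucleotide context), a
SEG-like allele-specific copy-number table (integer total and minor copy
number per segment, optional log2 ratio), and a sample sheet (group,
immunohistochemistry subtype, age, tumor purity, ploidy, panel size).
Read alignment, variant calling, functional annotation and segmentation
/ purity estimation are out of scope: their outputs are consumed as
given.  All on-disk coordinates are 1-based closed intervals (MAF/SEG
convention); every interval computation routes through two helpers in
`core.py` so the convention lives in one place.

Carrying the 3-mer context in the mutation table makes the package
self-contained (no genome FASTA download); an indexed FASTA is accepted
as a fallback context source.  Context lookups at chromosome edges are
excluded from spectra with a logged count, never silently dropped.

## Mutation burden

TMB counts missense, nonsense and silent SNVs plus all indels, divided
by the panel size in Mb.  The panel size is a required per-sample input
with no default — exome kits differ, and the value directly scales TMB.
The synthetic cohort uses 50 Mb, which makes a median of ~62 mutations
correspond to a median TMB of ~1.25/Mb, the regime typical of untreated
breast exomes.  TMB > 10/Mb flags a sample TMB-high (strict inequality).
Non-silent fractions are computed over all mutations; missense/nonsense
fractions are computed among non-silent SNVs.

## Spectra and signatures

SNVs are binned into the standard pyrimidine-centric 96 channels:
purine-reference variants are reverse-complemented, and channels are
ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then 5'
flank, then 3' flank, each in ACGT order.  Binned counts plus logged
exclusions always equal the input SNV count.

**Refitting** solves min ‖A·x − c‖² s.t. x ≥ 0 by active-set NNLS on the
raw count vector (A: 96 × S reference profiles, c: the spectrum), then
normalises x to fractions.  NNLS was chosen because it is the field's
standard refitting primitive and is verifiable against an exhaustive
grid search on small problems; exposures are scale invariant by
construction.  The reconstruction cosine between c and A·x is reported
as fit quality.  Refitting is per sample, not cohort-pooled.  By default
all bundled signatures are candidates; pass a restricted
`SignatureMatrix` to confine the fit.  A signature is called "positive"
in a sample when its fractional exposure strictly exceeds 0.10.

**De-novo extraction** uses Frobenius-loss NMF with multiplicative
updates (scikit-learn backend), best of `n_restarts` random
initialisations by reconstruction error; extracted profiles are
normalised to sum 1 with magnitudes absorbed into exposures.  The rank
is a parameter; `nmf_rank_survey` reports reconstruction error and
half-split stability over ranks 2–8, because no single selection rule is
canonical.  Extracted profiles are matched to the reference by cosine
similarity; below 0.8 a profile stays unassigned, the state representing
a potentially novel mutational process.

**The bundled reference matrix is synthetic.**  Real signature catalogs
are living, licensed resources; the package instead ships a
deterministic 30-profile stand-in (`signatures_v2like_synthetic.tsv`,
built by `scripts/make_synthetic_signatures.py`) whose named members
mimic the qualitative structure of well-known processes — a CpG C>T
age-related-like signature, TpC-focused APOBEC-like C>T and C>G
signatures, a near-flat HR-deficiency-like signature, a T[C>A]T
POLE-like signature, a broad MMR-like signature — with the remainder
drawn as sparse random simplex points at a fixed seed (maximum pairwise
cosine 0.61, so refitting and matching are well-posed).  All signature
analyses accept a user-supplied 96 × S TSV in the same layout.

## HRD genomic scars

Segments are first smoothed: pieces under 3 Mb are removed, flanks with
identical (total, minor) copy number are merged (gaps up to 3 Mb are
bridged — this covers both removed short segments and the centromere
split), and segments spanning the centromere are split into arm-local
pieces.  The three scar counts follow the canonical definitions:

- **LOH**: minor copy number 0, total ≥ 1, length strictly > 15 Mb,
  excluding whole-chromosome events (evaluated on the centromere-merged
  view so an event is measured at its true extent).
- **TAI**: allelic imbalance (major ≠ minor), touching a telomere
  (within 1 kb of position 1 or the chromosome end — exome segments
  rarely reach the literal end), not crossing the centromere, length
  ≥ 11 Mb.  The minimum size is configurable because the literature
  varies on whether one applies.
- **LST**: per chromosome arm, breakpoints between adjacent segments of
  different copy-number state with both flanks ≥ 10 Mb and a gap < 3 Mb.
  Counting is per arm (a cross-centromere pair can never qualify).

HRD score = LOH + TAI + LST; HRD-high at score ≥ 42 (inclusive).  All
size thresholds are keyword parameters with these defaults.  Boundary
conventions are strict for sizes (15 Mb exactly does not qualify as
LOH; 10 Mb exactly qualifies as an LST flank; 11 Mb exactly qualifies as
TAI) and inclusive for the 42 cutoff — each is unit-tested.

## Gene-level copy number

Each gene in the gene model receives the log2 ratio of its maximally
overlapping segment (ties broken toward larger |log2r|), derived as
log2(cn_total/2) when the segment table carries no log2 ratio column
(copy number 0 is floored at 0.5 to stay finite).  Calls use strict
thresholds: amplification > 0.9, gain > 0.2, loss < −0.2, deletion
< −0.9, else neutral; a gene with no overlapping segment is neutral
with a missing flag.  Recurrence is expressed as per-gene alteration
frequencies per group feeding a Fisher + BH family; peak-based
significance calling over cytobands is deliberately not implemented.

## Clonality

For a mutation with VAF f at a locus of total copy number n_t in a tumor
of purity p, multiplicity is estimated as
m = clamp(round(f/p · (p·n_t + 2(1−p))), 1, n_t) and the cancer cell
fraction as CCF = f · (p·n_t + 2(1−p)) / (p·m), capped at 2 for
reporting.  The VAF posterior under a uniform Beta(1, 1) prior is
Beta(alt+1, ref+1); its highest-density interval (the narrowest interval
holding the target mass, found by minimising width over the lower tail
mass) is mapped through the linear VAF→CCF transform.  The interval
level defaults to 0.95 and the depth floor to 8 reads; both are
configurable.  A mutation is Clonal when CCF = 1 lies inside its
interval.  Intervals entirely above 1 — an artifact of integer
multiplicity rounding — are also called Clonal, because a
super-clonal fraction is biologically impossible; a strict mode that
calls them Subclonal is available.  Mutations at homozygous-deletion
loci or below the depth floor are excluded with logged counts.

**Clustering.**  CCFs of copy-number-neutral mutations (n_t = 2, the
standard restriction for VAF-based clustering) are clustered with a 1-D
mixture fit by EM in which each observation's component variance is its
own read-sampling variance (the Beta posterior sd mapped to the CCF
scale, floored at 0.02), leaving only the k component means and k−1
weights free; k = 1..6 is selected by BIC with 2k−1 parameters.  Pinning
the variances matters: with free variances one wide Gaussian can absorb
several genuinely distinct clusters and BIC will prefer it at realistic
mutation counts.  Clusters holding under 2% of mutations are dropped and
proportions renormalised.  At least 10 eligible mutations are required;
otherwise the sample is flagged not assessable.  The Shannon index
H = −Σ p·ln p (natural log) over cluster proportions summarises
heterogeneity; H > 1 flags a heterogeneous tumor (three equal clusters
give ln 3 ≈ 1.10, two give ln 2 ≈ 0.69).

## Actionability

A frozen mini knowledge base ships with the package covering the
canonical breast-cancer actionable classes: ERBB2 amplification and
PIK3CA hotspot mutations (level 1 / ESCAT I), BRCA1/2 mutation or
deletion (level 1), PTEN deletion, AKT1 E17K, ESR1 and ERBB2 hotspot
mutations (levels 3–4 / ESCAT II).  Mutation entries match non-silent
mutations of the gene, optionally restricted to a hotspot list (protein
changes are read from a `GENE:p.X` gene field or a supplied mapping);
amplification/deletion entries match the corresponding gene-level calls.
Matching is deterministic and order-independent.  Summaries report
per-sample flags (any alteration, level 1–2, level 3–4, ESCAT I–II, two
or more alterations) and group percentages as flag means.  The KB format
is open; supply your own TSV for a different tumor type or an updated
catalog.

## Cohort statistics

Continuous features: Wilcoxon rank-sum, exact for pooled n ≤ 20 without
ties, otherwise normal approximation with tie correction; summaries as
median (range).  Binary features: Fisher's exact test with the two-sided
p defined as the sum of hypergeometric probabilities not exceeding the
observed table's (the convention of R's `fisher.test`) and the
conditional-MLE odds ratio.  Adjustment: logistic regression of the
group indicator on the feature plus subtype dummies and/or age, with the
Wald p-value and OR = exp(β) per feature unit reported; Wald rather than
likelihood-ratio because it is the default a practitioner reads off a
model summary, and the choice is labelled in the output.  Perfect
separation is flagged as unreliable rather than raised.  Multiple
testing uses Benjamini–Hochberg q-values, applied separately per family
(per-gene mutation frequencies, per-gene CNA frequencies, per-signature
comparisons) so one family cannot dilute another.

## Synthetic cohorts

The generator emulates the statistical structure each stage assumes, so
all stages are testable by parameter recovery.  Defaults describe a
two-group breast exome study:

| parameter | default | rationale |
|---|---|---|
| samples | 8 per group × subtype (48 total) | balanced three-subtype design at desk scale |
| mutations/sample | negative binomial, mean 90, dispersion 1.3 | long right tail; median ≈ 60, range extends to several hundred |
| depth | Poisson, mean 100× | typical exome coverage |
| purity | uniform 0.5–0.9 | FACETS-like estimates for breast tumors |
| panel | 50 Mb | median TMB ≈ 1.25/Mb at the default burden |
| signature mixture | age-related-like 0.30/0.40 (case/comparator), APOBEC-like 0.31/0.24, HRD-like 0.24/0.22, MMR-like 0.10/0.09, POLE-like 0.05 | dominant age-related process, slightly lower in the case group |
| clonal architectures | monoclonal / biclonal (1.0, 0.6+0.4) / triclonal (equal thirds) at 0.50/0.30/0.20 (case) vs 0.35/0.32/0.33 | more clonal case group; only the triclonal archetype is heterogeneous (H = ln 3 > 1) |
| scars | Poisson means (7,7,7) HR+, (8,8,8) HER2+, (13,13,13) TN, +2 each for TN cases | cohort median HRD score in the twenties, ~25% HRD-high, TN enrichment |
| focal CNAs | ERBB2 amplicon in 85% of HER2+ (3% otherwise), PTEN deletion 6%, BRCA1 deletion 3% | drives gene-level calls and actionability |

Scar-bearing profiles are *constructed from the written definitions*,
not from the scoring code: an LOH event is an interstitial 20 Mb (1,0)
segment, a TAI event a telomeric 12 Mb (3,1) segment, an LST event an
abutting 12 Mb (2,1)|(3,1) pair, each isolated by ≥ 4 Mb segment-free
gaps so no unintended breakpoint, telomere contact or merge can arise;
focal events are carved below the 3 Mb smoothing size so they influence
gene-level calls but not scar counts.  Mutations are placed only in
copy-number-neutral filler (so multiplicity is 1 and expected VAF =
CCF·p/2), with substitution channels drawn from the mixed signature
profile and emitted on a random strand.

**What passing tests show — and don't.**  Recovery tests demonstrate
internal consistency: the scorer counts exactly the events the written
definitions describe, refitting recovers planted mixtures, the credible
intervals are calibrated for binomial read noise, clustering recovers
planted architectures at 100× depth.  Real exomes violate the
generator's simplifications in known ways: segmentation error and
subclonal copy number (segments here are exact and clonal), purity
estimation error (purity here is known), multiplicity above 1 at
amplified loci (mutations here sit at diploid loci), sequencing error
and strand bias (reads here are ideal binomial draws), and signature
profiles correlated far more strongly than the synthetic catalog's.
Performance on real data will be correspondingly worse, especially for
clonality at low purity and for signatures with few mutations.

## Numerical choices and degenerate inputs

- HDI: bounded scalar minimisation of interval width over the lower tail
  mass, tolerance 1e-10; agrees with a 2×10⁶-draw Monte-Carlo oracle to
  three decimals.
- EM: tolerance 1e-9 on the log-likelihood, 300 iterations, three
  initialisations (quantile-based plus two seeded draws); values are
  sorted first, so results are independent of input order.
- NNLS degenerate case (nothing representable): uniform exposures with
  reconstruction cosine 0, rather than a crash.
- Empty samples yield all-zero burden rows with fractions as NaN;
  constant binary features compare with p = 1 and undefined OR; a
  single-group cohort skips the comparison stage with an explicit
  notice.
- All randomness (simulation, NMF restarts, EM initialisation) flows
  from explicit integer seeds; pipeline reruns are byte-identical.

## Known limitations

No indel or doublet signatures, no transcription-strand bias (SBS-96
only).  No re-implementation of segmentation, purity estimation or
peak-based CNA significance.  No multi-sample phylogenies or mutation
timing.  Clonality treats multiplicity as a point estimate; its
uncertainty is not propagated into the credible interval.  The bundled
gene model carries approximate loci for a compact panel of breast-cancer
genes and is meant for synthetic and demonstration work; supply a full
gene model TSV for real analyses.
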
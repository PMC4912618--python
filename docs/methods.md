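# Methods

This note records the models behind `crcclass`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Inputs and coordinate conventions

The pipeline consumes a per-mutation TSV (sample, gene, consequence
class, protein codon, isoform flag, variant allele fraction,
homopolymer run length, population frequency, panel-of-normals flag),
a per-sample clinical TSV (age, stage, site, specimen, assay MSI label,
metastasis flags, overall survival), a gene catalog (gene → canonical
protein length in amino acids), and an optional samples × genes log2
expression matrix. Protein positions are 1-based codons on one
declared canonical isoform per gene; for *APC* this is the 2,843-aa
canonical isoform. Mutations annotated on a variant isoform are kept
with `is_canonical_isoform=False`: they are excluded from truncation
counts and zone analyses but tallied separately, since alternative
transcripts can still be translated. A minimal MAF-column dialect is
provided; positions from other isoforms are stored as given (no
cross-isoform lift-over is attempted).

## Germline filtering and driver calls

Records with population frequency > 1% (configurable `max_pop_freq`)
or a panel-of-normals hit are removed; unannotated records pass. Only
two genes get restricted functional definitions: *APC* counts only
truncating events (stopgain or frameshift — the classes that destroy
the downstream β-catenin-binding repeats), and *BRAF* counts only the
codon-600 missense (V600E). Splice variants are deliberately *not*
treated as truncating. *KRAS* and *TP53* use any non-silent mutation.
If an alternative amino acid annotation is absent, any codon-600
*BRAF* missense is accepted as V600E.

The MSI proxy calls a tumour MSI-high iff both *TGFBR2* and *ACVR2A*
carry an indel in a homopolymer run of length ≥ 6
(`homopolymer_min_run`; the exact homopolymer definition used by
upstream annotation pipelines varies, so this is a config knob
surfaced in the run report). An assay label always takes precedence
over the proxy; discordances are logged.

## Significantly mutated genes

The background model is intentionally length-only: no covariates for
expression, replication timing or trinucleotide context. Counts *N*
are mutation **events**, not mutated samples (a gene can exceed the
cohort size; multi-hit tumour suppressors do). The robust line is an
MM-type fit:

1. Theil–Sen initial line (high breakdown, no tuning);
2. S-stage: bisquare M-scale at 50% breakdown (c = 1.547,
   consistency b = 0.5) coupled with reweighting steps;
3. final redescending bisquare M-step at c = 4.685 (95% Gaussian
   efficiency) with the S-scale fixed.

Residual z-scores use the robust scale, not the classical RMSE; the
intercept is free by default (`smg_fit_intercept`) because targeted
panels include UTR-adjacent and splice-region bait that decouples
counts from protein length near zero. Zero-count genes stay in the fit
(they inform the null line). Strata (overall / MSI / MSS) are fit
independently because hypermutated MSI tumours shift both slope and
scale; a stratum with fewer than 30 mutated genes is skipped.

**Known limitation (heteroscedasticity).** Under a Poisson null the
count variance grows with length, while the z-score divides by a
single global scale anchored near the typical gene. Genes several-fold
longer than the median therefore cross z = 3 by chance more often than
a Gaussian tail suggests: in null simulations (1,321 genes, study-like
rates) the z ≥ 3 fraction is ≈ 1.7% per cohort, concentrated in the
top length quintile, rather than ≤ 1%. This is a property of the
published statistic itself — very long genes flagged at low rates
should be treated with suspicion and cross-checked against an external
cohort, which is exactly what `compare_rates_to_reference` (two-sided
Fisher exact, discordance at p < 10⁻⁴) is for.

## APC profiling

Zones partition codons 1–2,843 as 1–218 / 219–1,262 / 1,263–1,587 /
1,588–2,843; the third zone is the mutation cluster region. Allelic
loss is inferred from any truncating event with VAF ≥ 0.50 (inclusive,
no tumour-purity correction — read fractions cannot distinguish loss
of heterozygosity from somatic recombination, and the call is
deliberately conservative about missing VAFs). For classification,
loss is consulted only in one-truncation tumours; the truncation count
is capped at 2 ("2" always means "2 or more"; tumours with > 2
truncations are rare and at least two of their hits must share an
allele).

The Poisson goodness-of-fit bins counts as {0, 1, 2, ≥3}, estimates λ
by the MLE over all tumours, and uses df = bins − 2; expected bins
below 1 merge into their neighbour. The zone-pairing test classifies
each exactly-two-hit tumour as both-early (zones 1–2), both-late
(zones 3–4) or one-each, with expectations from two independent draws
of the marginal zone-half distribution estimated over **all**
truncations (df = 2). Both tests are reported directionally; the
original binning behind the published p-values is not printed, so
digit-exact reproduction is not claimed.

## Classifications

The 10-group labels combine A (*APC* truncated), K, P and B. The
B/BP groups are BRAF-dominant **only when neither APC nor KRAS is
mutated** (the default precedence; `braf_dominant=True` sends every
V600E sample to B/BP). The choice matters rarely — V600E is strongly
anti-correlated with *APC*/*KRAS* — and the flag is always reported
alongside the label. The five-class scheme is a total function on
(apc ∈ {0,1,2+}) × kras × tp53 for MSS samples and is property-tested
as a partition; calling it on an MSI sample is an error by design.

## Association statistics

Percentile ranking: each focal gene's mutated-indicator is Spearman-
correlated with the target, and placed as a mid-rank percentile
(× 100/B) within the background of all genes carrying ≥ 5 non-silent
mutations. The percentile convention (mid-rank, ties averaged) is a
declared choice. Pairwise co-occurrence uses the two-sided Fisher
exact test; per-cell contingency flags compare each cell's (O−E)²/E
against χ²(1) quantiles at 0.05/0.01/0.001 with sign(O−E) giving the
arrow direction; trend tests across ordered groups use Cochran–
Armitage with equally spaced scores 0..k−1 for binary outcomes and an
OLS Wald slope test for continuous ones. No multiple-testing
correction is applied anywhere: selections are by z-score and
percentile, and raw p-values are reported.

## Signatures and two-sample tests

A signature score is the per-sample mean log2 expression over the
set's genes present in the matrix, with coverage reported; the matrix
is assumed log2-normalised upstream. The published EMT, RAS/MAPK and
64-gene β-catenin-target lists are not redistributable, so the package
ships synthetic stand-in sets (`default_gene_sets`) and reads real
lists from one-symbol-per-line files. Group comparisons use the
two-tailed Welch t-test (Satterthwaite df) and the exact Wilcoxon
rank-sum test (exact enumeration up to a combined n of 50, then the
continuity-corrected normal approximation with a logged note).

## Survival models

Kaplan–Meier, log-rank and Cox fits delegate to lifelines; ties use
the Efron approximation (survival times in months are heavily tied and
Efron is the accurate default). The late-age term is max(0, age−70) —
hazard increases only past 70, at `exp(β)` per year. Backward
elimination removes the unprotected covariate with the largest Wald p
until all are ≤ 0.10; no covariate is protected by default. The four
pre-specified MSS models are: (1) APC, KRAS, TP53, BRAF, Age≥70;
(2) + AKP + two-APC-mutations with elimination; (3) model 2 +
metastasis; (4) APC(2)KP replacing AKP and two-APC-mutations. The
five-class reference level, where used, is Class 1.

## The synthetic generator

`SyntheticConfig` defaults are the study conditions: n = 468;
MSI prevalence 61/468; proxy coupling sensitivity 59/61 and
specificity 0.99; MSS class mixture ∝ (111, 135, 76, 45, 40);
APC zone weights ∝ (3, 181, 259, 2) with two-hit tumours pairing one
early-zone and one cluster-region hit with probability 0.95;
one-hit allelic-loss probability 59/187; VAF ~ truncated normal
(mean 0.60 with loss, 0.35 without, sd 0.08, bounds [0.05, 0.95]);
background non-silent loads Poisson with means 169 (MSI) and 33 (MSS)
split across genes ∝ 3·length, silent:non-silent 1:2.8; exponential
survival with baseline median 60 months and log-hazards from the final
prognostic model (HRs 0.59 / 2.25 / 2.10 / 4.49 / 1.09 per year); and
uniform censoring on [6, 62] months giving a ~34-month median
follow-up among the living. Driver co-occurrence is induced by the
class mixture (MSS) and a BRAF-given-MSI probability of 52/61 rather
than a free correlation matrix — enough to reproduce the sign
structure of the published associations. Where the study prints no
value (KRAS/TP53 conditionals within classes, age distribution
N(64, 12²) truncated to [25, 95], stage-given-metastasis mechanics),
the defaults are single realistic choices documented in
`SyntheticConfig` and not revisited.

The generator emulates marginal and pairwise structure, not sequence:
no reads, no positions beyond codons, no tumour purity, no
subclonality, no site-specific hotspot spectra, and expression shifts
are additive Gaussian on synthetic gene sets. Passing recovery tests
therefore show that the pipeline inverts the assumed generative
structure — not that the assumptions hold in real tumours.

Problem sizes in the test and acceptance suites (100 null cohorts of
1,321 genes for the detection operating characteristics, 500
replicates per calibration check, 200 replicates of n = 4,070 for the
hazard-ratio coverage, one n = 4,070 cohort for the headline
recomputation) were chosen as the smallest scales at which the
binomial/Monte-Carlo error of each check is comfortably below its
tolerance.

## Degenerate inputs and tie-breaks

Empty optional fields are absent, not zero; unparsable codons become
absent with a warning count; exact-duplicate mutation rows collapse
(same-codon different-class rows are distinct events); orphan samples
and unknown enums are hard errors. The Poisson GOF refuses fewer than
3 distinct counts; the pairing test refuses < 5 two-hit tumours; the
robust fit refuses < 30 genes or a constant-length catalog; Wilcoxon
returns p = 1 for identical samples; Fisher returns p = 1 with a
warning on an empty margin.
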
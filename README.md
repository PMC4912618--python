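# crcclass

Multigene somatic-mutation classification and prognosis for colorectal
cancer (CRC) cohorts.

Colorectal tumours are routinely staged clinically, but their outcome
varies widely within stages. `crcclass` implements a mutation-centric
classification pipeline for targeted-panel cohorts: it turns annotated
per-mutation tables into per-sample driver calls, screens the panel for
significantly mutated genes, profiles *APC* two-hit status, assigns the
10-group and five-class driver classifications, and quantifies their
prognostic value with Kaplan–Meier and Cox proportional-hazards models.
Because the motivating patient-level data are controlled-access, the
package ships a fully parameterised synthetic-cohort generator so that
every stage is testable end to end.

## The statistics at the core

**Significantly mutated genes.** Across a targeted panel the non-silent
mutation count *N<sub>g</sub>* of gene *g* scales with its coding
length. The background is fit by MM-type robust regression
(Theil–Sen start, bisquare S-scale, 95%-efficiency bisquare M-step)

&nbsp;&nbsp;&nbsp;&nbsp;*N<sub>g</sub>* ≈ *a* + *b* · AA<sub>g</sub>,&nbsp;&nbsp;
*z<sub>g</sub>* = (*N<sub>g</sub>* − *â* − *b̂*·AA<sub>g</sub>) / *ŝ*,

and genes with *z* ≥ 3 in any stratum (overall, MSI, MSS) are flagged.
Per-gene rates are reported per 10⁵ coding nucleotides:
rate = 10⁵·*N* / (*n*·3·AA).

**MSI proxy.** A tumour is called microsatellite-unstable iff it
carries homopolymer-region indels in **both** *TGFBR2* and *ACVR2A*;
an assay label, when present, overrides the proxy.

**APC two-hit profile.** Truncating mutations (stopgain/frameshift on
the canonical isoform, 2,843 aa) are placed into four zones
(1–218, 219–1,262, 1,263–1,587 = mutation cluster region,
1,588–2,843); allelic loss is inferred when a truncation's variant
allele fraction is ≥ 0.50. A χ² goodness-of-fit tests the per-sample
truncation counts against a Poisson law, and a pairing test asks
whether two-hit tumours combine one early-zone with one
cluster-region hit.

**Classifications.** Samples are labelled by driver combination
(WT, B, BP, K, P, KP, A, AK, AP, AKP over *APC*/*KRAS*/*TP53*/*BRAF*
V600E), and MSS samples by the prognostic five-class scheme —
C0: *APC*wt; C1: *APC*(1); C2: *APC*(2+); C3: *APC*(1)/*KRAS*/*TP53*;
C4: *APC*(2+)/*KRAS*/*TP53* — where "(2)" means two or more truncations.

**Survival.** Cox models (Efron ties, lifelines backend) with a
piecewise-linear Age≥70 term (0 below 70, age−70 above) and Wald-p
backward elimination (stay level 0.10); four pre-specified model
variants culminate in Model 4: *APC*, *BRAF*, *APC*(2)KP, distant
metastasis, Age≥70.

## Worked example

```bash
crcclass simulate --seed 1 --n-samples 468 --out-dir demo_out
```

generates a synthetic 468-tumour cohort and runs every stage. With this
seed the run reports (in `demo_out/`):

* `five_class_counts.tsv` — MSS class sizes `C0 103, C1 127, C2 81,
  C3 45, C4 43` (n=399 MSS), multinomial scatter around the generative
  mixture 111/135/76/45/40;
* `apc_tests.json` — Poisson goodness of fit p ≈ 1.4 × 10⁻¹⁵ (strong
  excess of exactly-two-hit tumours) and zone-pairing p ≈ 4 × 10⁻²⁷
  (129/132 two-hit tumours pair an early-zone with a cluster-region
  hit);
* `cox_models.json` — Model 4 on the MSS subset keeps
  `apc HR 0.66, braf 1.96, apc2kp 1.66, metastasis 4.51, age70 1.08`
  after eliminating `kras`/`tp53`, LR χ² ≈ 124: the generative hazard
  ratios (0.59 / 2.25 / 2.10 / 4.49 / 1.09) recovered at cohort scale.

The same stages run on user tables via
`crcclass all --mutations m.tsv --clinical c.tsv --catalog g.tsv`.

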
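# Methods

This note documents the statistical model behind `pdpathways`, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## The two study arms

**GWAS arm.** SNP associations enter as summary statistics (id, chromosome,
1-based position, p-value). Mapping uses a closed window: a gene is
assigned when its inclusive interval [start, end] intersects
[pos − w, pos + w] with w = 20 000 bp by default, so a gene whose boundary
lies exactly w away is still assigned. When the window is empty the nearest
protein-coding gene strictly left and strictly right are both assigned,
irrespective of distance (one side may be missing near a chromosome end);
equidistant ties on a side go to the lexicographically smaller gene id so
runs are deterministic. SNPs on chromosomes absent from the annotation
contribute nothing but are counted in a warning — silently dropping them
would hide annotation mismatches. The query universe is built from the top
SNPs (p < 0.01, strictly, at most 5000, ties at the cutoff broken by SNP
id) and the reference from all SNPs, both with set semantics so
linkage-driven SNP multiplicity cannot double-count a gene.

**Expression arm.** Input is a complete log2 expression panel
(gene × subject × region), regions ordered by Braak stage. The design
deliberately avoids cross-subject region comparisons: each subject is their
own baseline. Raw delta = value(later region) − value(earlier region) for
each consecutive pair; control subjects are treated as replicates and their
per-(gene, pair) mean delta is subtracted from each case's delta. Because
every individual and region pair is unique there is no within-cell
replication, so a t-test or ANOVA across subjects is not applicable; the
only available null spread is the control replicate distribution. We test

    z = Δ_adj / (s_ctrl · sqrt(1 + 1/n_c)),   p = 2 Φ̄(|z|)

where s_ctrl is the sample sd (ddof = 1) of the n_c control deltas and the
sqrt term propagates the sampling error of the control mean. This z-test is
an interpretation — the underlying workflow specifies the subtraction and
the Benjamini–Hochberg q < 0.05 / 1.6-fold gates but not the test itself.
With few controls the normal reference is anti-conservative (the exact null
of z is Student t with n_c − 1 df); see *Limitations*. BH runs across genes
within each (subject, pair) stratum, mirroring the one-subtraction-at-a-time
workflow; an alternative would be a single correction across all strata.
Genes with zero control variance are uncallable (p = 1), not infinitely
significant. The fold threshold is linear-scale: |Δ_adj| ≥ log2(1.6). The
up and down lists are unioned into the merged list consumed downstream; a
gene may legitimately appear in both.

## Enrichment and meta-analysis

Over-representation uses the inclusive hypergeometric upper tail
P(X ≥ k). For universes up to 500 genes the tail is computed in exact
rational arithmetic; above that, as a sum of log-space pmf terms (error
well below 1e-12 over the sizes used here). Query genes outside the
reference are trimmed with a warning rather than failing; pathways with no
reference members are reported as untested rather than p = 1 (a p of 1
would silently deflate the Bonferroni multiplier downstream). No
within-study multiple-testing correction is applied — only the combined
p-values are corrected. Per-study significance is inclusive, p ≤ α with
α = 0.05.

Fisher's combination uses χ² = −2 ln(p₁p₂) with 4 degrees of freedom (two
independent tests × 2 df). The survival function is evaluated by scipy's
chi-square; for df = 4 it equals p₁p₂(1 − ln p₁p₂), which the tests use as
an independent closed-form oracle. Inputs are required to be in (0, 1];
enrichment p-values are floored at 1e-300 so the log is defined, and values
above 1 by rounding (≤ 1e-9) are clamped with a warning. The Bonferroni
multiplier M is the number of pathways tested in **both** arms, not the
catalogue size: that is the standard universe for the tests actually
performed, and it is the only multiplier consistent with published
(meta p, corrected p) pairs in this design, which imply an integer ratio
recoverable by `infer_bonferroni_multiplier` (median of uncapped
corrected/raw ratios, required to agree within 2%). Ranks are ascending in
p_meta with ties broken by pathway id. Pathways tested in a single arm are
listed separately as uncombined rather than imputed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any real genome:

| parameter | default | rationale |
|---|---|---|
| genes / chromosomes | 2000 / 4 | smallest universe where the 5000-SNP / 20 kb design behaves as in a genome-scale run |
| gene length / gap | Exp(10 kb) / Exp(15 kb) | typical protein-coding gene scale; non-overlapping by construction |
| pathways | 200 × 50 genes, 1 planted | catalogue of order 200 human pathways; fixed size keeps the null exchangeable |
| SNPs | 20 000 uniform over chromosome spans | ~0.4 SNP/kb, so each gene's ±20 kb window holds ~20 SNPs |
| planted SNP p | Beta(a=0.2, 1) within 20 kb of planted genes | one-parameter small-p enrichment with closed-form mean a/(a+1), so tests have analytic oracles |
| expression | baseline N(8, 1.5²) + region offsets (0, 0.4, −0.3, 0.6, 0.2) + case-only cumulative shift 1.0 log2/transition on planted genes + N(0, 0.3²) noise | additive in log2 space, matching the subtraction design's implicit additivity; offsets are the "normal between-region variation" the control adjustment removes |
| subjects | 7 cases / 4 controls | the regional-panel scale this design targets |

Each generator draws from `default_rng([seed, offset])` with a fixed
per-generator offset, so changing one component's size never perturbs
another's draws; every output is byte-reproducible under a seed. The `null()`
variant sets a = 1 (uniform p everywhere) and stage shift 0.

Not modelled: linkage disequilibrium (SNPs are independent), allele
frequencies, probe-level microarray noise, gene-length confounding of SNP
counts, correlated pathway membership beyond random sharing. Passing the
recovery benchmark therefore shows the pipeline's machinery is correct and
calibrated under its own assumptions — not that real PD cohorts of this
size would yield the same power.

## Numerical and procedural choices

* Coordinates 1-based inclusive throughout (dbSNP/ENSEMBL convention);
  window intersection inclusive at exactly w.
* Expression values are log2 by contract; readers never transform, and any
  missing (subject, region) cell is a hard error — the subtraction design
  is undefined with missing regions, so nothing is imputed.
* Determinism: all orderings that reach output files are total (p-value
  then id), so reruns are byte-identical; the run manifest records sha256
  digests of every input and output and is written atomically.
* Problem sizes in the test suite and acceptance script (50/20-seed sweeps
  at the default conditions, 10/5-seed sweeps in the analysis drivers) were
  chosen to estimate the binary recovery fractions and medians to within a
  few percent.

## Limitations

* With n_c = 4 controls, z is exactly t(3)-distributed under the null, so
  the two-sided normal p is anti-conservative in the tails: the observed
  null call rate is ~3–4% of (gene, subject, pair) tests at q < 0.05
  (within the documented ≤ 8% allowance), and accumulated over 7 subjects ×
  4 pairs roughly half of all null genes enter the merged list at the
  default panel size. Pathway-level inference remains calibrated — the
  hypergeometric test conditions on the realised list size n, and the null
  sweep's median pathway p sits near 0.5 — but the merged *gene* list has
  low per-gene specificity and should not be read as a validated gene-level
  call set. A t(n_c − 1) reference would fix gene-level calibration at the
  cost of departing from the documented normal-z design.
* The Bonferroni multiplier inference assumes at least one uncapped
  corrected p-value and printed precision of ~3 significant figures.
* The pipeline consumes already-normalised log2 matrices and existing
  summary statistics; normalisation, imputation and association testing are
  upstream of its contract, as are pathway-database retrieval and
  cross-pathway topology.
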
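# apobecsig

APOBEC-mutagenesis analysis for somatic SNV catalogs, built around the
question of whether APOBEC activity marks non-small-cell lung cancers
(NSCLC) that respond durably to anti-PD-1 immunotherapy. The package is a
library first (with an `examples/` directory of narrative scripts) plus a
thin `apobecsig` command-line wrapper for batch runs.

APOBEC cytidine deaminases attack cytosines in single-stranded DNA within
the TCW trinucleotide motif (W = A or T), leaving C>T transitions and C>G
transversions at TCA/TCT sites. The package quantifies that footprint and
its clinical utility in four stages:

**1. Mutation spectra.** Somatic SNVs (MAF or single-sample VCF) plus an
indexed reference FASTA become per-sample 96-channel trinucleotide spectra
(6 pyrimidine substitution classes × 16 flank pairs; purine-reference
mutations folded onto the reverse complement).

**2. APOBEC metrics.** Per sample, the TCW mutation count, the fold
enrichment of TCW mutations over the local sequence context,

```
E = [ (TCW→TGW + TCW→TTW) / (C→G + C→T) ] / [ TCW / C ]
```

with the motif denominators TCW and C counted over the ±20 nt reference
windows around each mutated cytosine, and the minimum APOBEC mutation load

```
min_load = round( (TCW→TGW + TCW→TTW) × (E − 1)/E )
```

— the number of TCW mutations in excess of random mutagenesis. At E = 2,
exactly half of a sample's TCW mutations are attributable to APOBEC.

**3. De novo signatures.** Bayesian NMF under a Poisson/KL objective with
automatic relevance determination factorizes the cohort catalog V ≈ WH,
shrinking superfluous components to zero so the number of signatures K is
selected automatically; restarts quantify rank recurrence, and cosine
similarity matches the extracted signatures to a COSMIC-v2-style reference
(the APOBEC signatures are 2 and 13).

**4. Biomarker statistics.** TCW count vs total mutation count as
predictors of durable clinical benefit (DCB vs NDB): univariate logistic
regression, the Hosmer–Lemeshow calibration test (g equal-count bins of
fitted probability, χ² with g − 2 df), group means and fold changes,
quartile UP/DOWN expression grouping, t/Wilcoxon comparisons with
Benjamini–Hochberg correction, and Spearman association of signature
exposures with an immune-gene-module score.

A fully synthetic cohort generator (reference sequence with controllable
TCW density, signature-mixture mutation catalogs, logistic-link DCB/NDB
labels, exposure-linked expression matrix) makes every stage testable
end to end without downloads.

## Worked example

`python examples/04_biomarker_comparison.py` simulates a 40-patient cohort
whose DCB labels are driven by APOBEC load and compares the biomarkers:

```
tcw_count: DCB mean 33.8 vs NDB mean 10.0 (3.4-fold), H-L p = 0.154
total_count: DCB mean 194.7 vs NDB mean 297.5 (0.7-fold), H-L p = 0.516
```

Patients with durable benefit carry 3.4-fold more TCW (APOBEC-context)
mutations, while total burden barely separates the groups; the H-L
p-values say both fitted logistic models are acceptably calibrated (small
p would mean poor fit). `examples/02_apobec_enrichment.py` prints
per-sample enrichment, e.g.:

```
SYN003          59.0       4.213        45    0.000
SYN006         125.0       4.645        98    0.000
```

— sample SYN006 has 125 TCW mutations, 4.6-fold enriched over its local
context, of which at least 98 are attributable to APOBEC. The other
examples cover spectra (`01`), signature extraction with rank selection
(`03`), and the full pipeline bundle (`05`).

The same stages are available from the shell:

```bash
apobecsig simulate --seed 7 --outdir cohort/
apobecsig run-all --maf cohort/cohort.maf --fasta cohort/reference.fa \
    --clinical cohort/clinical.tsv --outdir results/ --seed 7
```

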
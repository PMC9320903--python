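# trioscan

Trio-exome analysis toolkit for isolated congenital heart defect (CHD)
cohorts. Implements, as a tested and reusable pipeline:

- **Trio classification** — high-quality de novo variant calling from joint
  genotypes (QUAL > 300 for SNVs / > 1000 for indels, parental hom-ref with
  GQ ≥ 30, cohort recurrence ≤ 2) and high-quality inherited variant
  classification, multi-nucleotide variant merging, rare (gnomAD AF ≤ 0.1%)
  damaging-variant annotation against gene constraint (oe upper bound
  < 0.35), CADD (≥ 25), embryonic cardiac expression (≥ 2 TPM in at least
  one 4–8 wpc stage) and CHD gene panels.
- **Mosaic post-filtering** — conjunction filter on externally supplied
  mosaic candidates (posterior ≥ 0.90, VAF 0.10–0.40, ≤ 2 parental alt
  reads per parent, recurrence ≤ 2, LOF/missense), with per-criterion
  verdicts and relevance annotation.
- **TDT** — transmission disequilibrium testing of rare damaging parental
  alleles at gene and panel level, exact-binomial (default) or chi-square
  statistic, gated at ≥ 5 informative alleles, BH FDR per family.
- **Burden association** — CADD-weighted variant fraction
  (VF = Σ VAC·CADD/10) in a logistic model with PC1 as covariate, tested by
  likelihood ratio, gated at ≥ 5 alleles, BH FDR; GRM-based relatedness
  exclusion of controls and native PCA for population structure.
- **Synthetic cohort generator** — trio + control cohorts with Mendelian
  transmission, configurable transmission distortion, burden enrichment,
  de novo / mosaic injections, population structure, related control pairs
  and quality noise, all with a ground-truth table for recovery testing.

## Layout

| module | contents |
|---|---|
| `trioscan.core` | domain types (site calls, annotations, pedigree), VCF/TSV readers and writers, consequence classification |
| `trioscan.synthetic` | cohort simulator and fixture-bundle writer |
| `trioscan.mosaic` | mosaic candidate filter and relevance evaluation |
| `trioscan.trio` | HQ de novo / inherited classification, MNV merging, per-proband report |
| `trioscan.panels` | gene panels, expression table, expression/damaging predicates |
| `trioscan.tdt` | transmission counting and disequilibrium tests |
| `trioscan.burden` | GRM, relatedness exclusion, PCA, variant fraction, logistic LRT |
| `trioscan.pipeline` / `trioscan.cli` | end-to-end orchestration, cohort summary, CLI |

## CLI

Everything is driven by `ichd-trioscan`:

```sh
# generate a synthetic cohort with known truth
ichd-trioscan simulate --out sim/ --seed 7

# classify rare damaging de novo variants
ichd-trioscan classify-dnv --vcf sim/callset.vcf --ped sim/pedigree.tsv \
    --annotations sim/annotations.tsv --constraint sim/constraint.tsv \
    --expression sim/expression.tsv --panels-dir sim/panels --out dnv.tsv

# TDT and burden association
ichd-trioscan tdt    ... --level panel --variant-class missense --out tdt.tsv
ichd-trioscan burden ... --level gene  --variant-class lof      --out at.tsv

# full pipeline from one JSON config
ichd-trioscan all --config pipeline.json --seed 7
```

A pipeline config is a single JSON document; every threshold (QUAL, GQ, AF,
CADD, oe, TPM, VAF window, gates, FDR level) is surfaced under
`thresholds` with the published defaults, so sensitivity analyses are
one-line edits:

```json
{
  "out_dir": "run/",
  "sim": {"n_trios": 73, "n_controls": 300, "defect_labels": {"TGA": 11}},
  "thresholds": {"gq": 30},
  "seed": 7
}
```

Real cohorts are run by replacing `sim` with `inputs` (paths to `vcf`,
`pedigree`, `annotations`, `constraint`, `expression`, `panels_dir`,
`mosaic_candidates`).

## Input formats

Multi-sample VCF 4.2+ with `GT:GQ:AD` (multi-allelic records are decomposed
at ingest; half-calls count as missing); tab-separated annotation,
constraint, expression and pedigree tables with one header line; gene
panels as one-symbol-per-line text files. See `trioscan.core` docstrings
for column names.
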
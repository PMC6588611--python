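# germscreen

Germline predisposition screening for advanced-cancer cohorts, as a
tested, reusable pipeline:

1. **Filter cascade** (`germscreen.germline_filter`) — four independent
   stages: call quality ≥ 20 and depth ≥ 10; population allele frequency
   ≤ 1% (unless a known pathogenic common variant); coding
   non-synonymous or splice-site (±2 bp) consequences; sample VAF > 20%.
2. **Pathogenicity classification** (`germscreen.variant_classifier`) —
   deterministic five-class engine: curated assertions override
   everything; loss-of-function consequences in panel genes are class
   5 when absent from population databases (class 4 otherwise);
   missense defaults to VUS. Includes recessive-gene handling
   (heterozygous singletons diverted, homozygous and potential compound
   heterozygotes kept) and carrier counting.
3. **Tumor integration** (`germscreen.tumor_integration`) — LOH calling
   (tumor VAF > 65%, strict), somatic second hits with phase analysis,
   and reversion detection (cis somatic indel restoring the reading
   frame: combined net length ≡ 0 mod 3).
4. **Pathway burden** (`germscreen.pathway_burden`) — variant-level
   pathway distributions (Fanconi genes count toward the HR super-group)
   and per-cancer-type carrier fractions.
5. **HRD expression classification** (`germscreen.hrd_expression`) —
   signature-restricted two-way hierarchical clustering, provisional
   labels (lower signature centroid → deficient), KNN classifier with
   leave-one-out predictive value, and co-occurrence summaries.
6. **Clinical report** (`germscreen.clinical_report`) — clinical
   significance groups 1–3, treatment suggestion (PARPi for BRCA1/2,
   immunotherapy for MMR genes), return-of-results recommendation, and
   the full cohort summary tabulation.
7. **Synthetic cohorts** (`germscreen.synthetic_cohort`) — seeded
   generator of patients, germline calls (with single-violation filter
   decoys), tumor observations under variable purity, and two-group
   expression matrices, plus a ground-truth table for recovery testing.

A packaged 168-gene default panel ships with the package
(`germscreen.io_core.default_panel`). It is a *reconstruction* — the
original list is not public — and is fully user-replaceable via
`--panel` / `read_panel`. The HRD/PARPi signature gene lists are
likewise user-supplied (one symbol per line).

## CLI

```bash
# generate a synthetic cohort
germscreen simulate --n-patients 636 --carrier-fraction 0.178 --seed 1 --out data/

# full pipeline (HRD stage runs only when an expression matrix is given)
germscreen run \
  --variants data/variants.tsv --patients data/patients.tsv \
  --tumor data/tumor.tsv --seed 1 --out results/

# individual stages
germscreen filter --variants data/variants.tsv --out results/
germscreen simulate-expression --effect-size 3 --out expr/
```

`run` writes: `filter_trace.tsv`, `second_hits.tsv`, `hrd_calls.tsv`,
`assessments.tsv`, `cancer_type_frequency.tsv`, the summary tables,
`run_report.json`, and the verbatim `run_config.json` for provenance.
Outputs carry no timestamps; identical inputs and seed give
byte-identical outputs.

Input formats: variant calls as TSV (see
`germscreen.io_core.VARIANT_COLUMNS`) or minimal VCF 4.x (CHROM, POS,
REF, ALT, QUAL, FORMAT DP/AD; consequence annotation must arrive via
TSV). Population allele frequency is a single pre-aggregated maximum
across databases. All coordinates are 1-based (VCF convention); VAFs
are fractions, percentages appear only in reports (round half away from
zero).

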
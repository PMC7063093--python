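# genoquery

A sample-centric genotype query engine for multi-sample VCF cohorts:
build a Word-Aligned Hybrid (WAH) compressed bitmap index over the
genotypes once, then run inheritance-model, case-control, and
population-contrast variant filters against it.

## Who it is for

Groups sitting on large merged VCFs (families plus control cohorts, or
multi-population panels, human or not) who repeatedly ask sample-centric
questions — *which variants fit a recessive model in this trio and are
rare in our controls?* — without wanting to rescan the whole file per
query. Variants can be SNVs, indels, or anything else VCF encodes with a
GT field.

## The model

Every genotype collapses to four states — `HOM_REF`, `HET`, `HOM_ALT`
(≥ 2 ALT alleles), `UNKNOWN` (any missing allele). The variant-centric
matrix is transposed so each sample owns four bitmaps over the variant
axis, variants are sorted by descending non-reference allele count to
lengthen runs, and each bitmap is WAH-compressed (32-bit words; literal
words carry 31 bits, fill words run-length encode all-0/all-1 groups).
Filters are conjunctions of per-sample state tests (compressed-domain
AND/OR) plus counting primitives:

* `pct(S, state) = count / |S|` — fraction of individuals in a state,
* `maf(S) = (n_HET + 2·n_HOM_ALT) / (2·n_called)` — alternate-allele
  frequency over called genotypes.

Eleven filter models cover pedigree analysis (recessive, compound
heterozygous, dominant, recessive/dominant de novo), case-control studies
(case-specific, cases shared), and population comparisons
(allele-frequency, individual-count, by-sample, variant count), with a
control-cohort MAF cutoff and missing-genotype rescue for affected
samples available throughout. Sample roles come from a tab-separated PED
dialect (`IndividualID`, `Phenotype`, `Sex`, `Population`; phenotype
0 = excluded, 1 = control, 2 = case, 3 = carrier/affected parent).
Details and design rationale: `docs/methods.md`.

## Worked example

```python
from genoquery import (CohortSpec, generate_cohort, build_index,
                       create_sample_db, parse_ped, filter_recessive)

spec = CohortSpec(seed=42, n_variants=2_000, n_controls=50,
                  planted=[("recessive", 5, {}), ("compound_het", 4, {})])
cohort = generate_cohort(spec)            # trio + 50 controls, VCF-ready
index = build_index(cohort.records, cohort.matrix)
```

Running `python examples/trio_filtering.py` (this code plus the
compound-het query) prints:

```
cohort: 2000 variants x 53 samples
recessive candidates (control MAF = 0): 5
  planted recessive sites recovered: 5/5
compound-het candidates: 4
  planted compound-het sites recovered: 4/4
```

The five recessive candidates are exactly the planted sites where both
parents are `HET`, the child is `HOM_ALT`, and the 50-control MAF is 0;
the four compound-het candidates are the planted `HET` child sites with
exactly one carrier parent. `examples/population_contrast.py` and
`examples/index_and_report.py` walk the population queries and the
index-file/annotation-summary workflow the same way.

The same pipeline from a shell:

```sh
genoquery simulate work/ --seed 42 --n-variants 2000 --plant recessive:5
genoquery index work/cohort.vcf work/cohort
genoquery makedb work/cohort.ped work/cohort work/samples.db
genoquery query work/cohort work/samples.db --model recessive \
    --maf-max 0 --out-vcf hits.vcf --out-table hits.tsv
```

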
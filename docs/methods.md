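# Methods

## The problem

Cohort resequencing projects accumulate multi-sample VCFs with thousands of
samples and millions of sites. The questions geneticists actually ask of
such a file — "which variants are heterozygous in both carrier parents and
homozygous in the affected child, and rare in our controls?" — are
*sample-centric*: they compare a handful of individuals across every locus.
A VCF is variant-centric; answering a sample-centric question from it means
touching every row while using only a few cells per row.

`genoquery` addresses this by transposing the genotype matrix into a
per-sample bitmap index, compressing it, and expressing every filter model
as boolean algebra plus counting over those bitmaps.

## Genotype model

Each genotype call collapses to one of four states:

| code | state | meaning |
|---|---|---|
| 0 | `HOM_REF` | no ALT alleles |
| 1 | `HET` | exactly one ALT allele |
| 2 | `HOM_ALT` | two or more ALT alleles |
| 3 | `UNKNOWN` | any missing allele (`.`) |

Design choices where VCF is richer than four states:

* **Multi-allelic sites are not split.** The state is the count of
  non-reference alleles over all ALT alleles, so `1/2` is `HOM_ALT` and
  `0/2` is `HET`. This keeps one site = one bitmap position, which the
  whole index design assumes.
* **Half-calls** (`./1`) are `UNKNOWN` — a partially missing call cannot
  prove either presence or absence, so it is treated conservatively.
* **Haploid calls** (chrX/chrY in males) map to `HOM_REF`/`HOM_ALT`.
* **Phasing is ignored**; `|` and `/` are equivalent. The compound-
  heterozygous model therefore works at the single-variant level (see
  below), not on haplotypes.

## The index

1. **Transpose** — each sample becomes four class bitmaps (one per state)
   over the variant axis; for every position exactly one of the four bits
   is set (the *partition property*), which makes the index lossless.
2. **Allele-frequency sort** — variants are ordered by descending
   non-reference allele count (UNKNOWN contributes nothing; ties keep
   input order). Grouping sites of similar frequency concentrates the 1s,
   lengthening the constant runs the compressor exploits. A permutation
   (`.vid` file) restores input order on output, so the sort direction has
   no observable effect on results.
3. **WAH compression** — Word-Aligned Hybrid coding with 32-bit words: a
   literal word carries 31 payload bits; a fill word (flag bit, fill bit,
   30-bit run count) represents up to 2³⁰−1 consecutive all-0 or all-1
   31-bit groups. AND/OR/NOT run directly on the compressed streams,
   consuming a fill of any length in one step. Word width 32 is the
   classic choice for this scheme; the last partial group is zero-padded
   and the logical length is stored, so decompression is exact.

The index persists as three files with a shared prefix — `.gqt` (bitmaps,
binary little-endian), `.bim` (variant metadata in sorted order,
gzip-compressed TSV), `.vid` (the permutation) — each opening with a magic
string and format version. The layout is this package's own; compatibility
with any other tool's index files is a non-goal.

Cross-sample counting decompresses per-sample state vectors into machine
words and sums them with numpy; group conjunctions ("every parent is HET")
stay in the compressed domain. Correctness, not a particular counting
trick, is the contract — the suite checks every model against a naive
variant-centric scan.

## Filter models

Sample roles come from a PED-dialect roster: tab-separated, first line a
header naming `IndividualID` and, per use, `Phenotype` or
`Population`/`Sex`. Phenotype coding: 0 = excluded from everything,
1 = unaffected control, 2 = affected offspring (case), 3 = affected or
carrier parent. Index samples absent from the PED default to 0 — silent
inclusion would corrupt MAF denominators. One PED describes one family per
query: a trio condition applies to *all* Phenotype-3 samples jointly.

Per-variant primitives over a selected sample set *S*:

* `count(S, states)` — number of samples whose state is in the set;
* `pct(S, states)` — `count / |S|` (UNKNOWN carriers stay in the
  denominator: the question is "what fraction of the individuals");
* `maf(S)` — `(n_HET + 2·n_HOM_ALT) / (2·n_called)` with
  `n_called = |S| − n_UNKNOWN` (an allele frequency is over called
  alleles). If no sample is called the value is 0 and flagged uncalled.

The eleven models (thresholds inclusive — "at least"/"at most"):

| model | keep a variant iff |
|---|---|
| recessive | all P3 `HET` and all P2 `HOM_ALT` |
| compound het | all P2 `HET`, exactly one of the two P3 `HET` and the other `HOM_REF`; ≥ 2 candidates must survive, else the result is empty with a note |
| dominant | all P3 and all P2 `HET` |
| recessive de novo | all P3 `HOM_REF`, all P2 `HOM_ALT` |
| dominant de novo | all P3 `HOM_REF`, all P2 `HET` |
| case-specific | all P2 in chosen states (`HOM_ALT`/`HET`/both), all P1 `HOM_REF` (UNKNOWN tolerated with the control-missing flag) |
| cases shared | all P2 in chosen states (may include `UNKNOWN`); controls touched only via `maf_max` |
| population allele-frequency | `maf(A) ≥ maf_min` and `maf(B) ≤ maf_max` |
| population individual-count | `pct(A, state) ≥ pct_min%` and `pct(B, state) ≤ pct_max%` |
| by-sample | `count(chosen samples, states) ≥ count_min` |
| variant count | popcount of one sample's state bitmap (no records materialised) |

Cross-cutting parameters:

* **`maf_max`** (fraction) caps the MAF among Phenotype-1 controls; with
  no controls present it no-ops with a logged warning. Population
  percentage thresholds are given in percent (0–100) to match how such
  queries are phrased; MAF thresholds are fractions.
* **Missing-genotype rescue** (`allow_missing`) lets `UNKNOWN` in
  *affected* (Phenotype-2) samples satisfy the required state, recovering
  candidates lost to low coverage. Parents and controls are never rescued:
  an uncalled parent cannot demonstrate the absence a de novo model
  requires. "Homozygous" in the recessive model means `HOM_ALT` (the
  carrier-parent context forces it); "wild type" in compound het means
  `HOM_REF`.

The compound-heterozygous model is single-variant: it cannot verify that
two candidates sit on opposite haplotypes, and it applies the ≥2 rule
globally rather than per gene (per-gene grouping when annotation is
present is noted as future work).

## Reporting

Results return in input file order (the `.vid` permutation inverts the
frequency sort). Output: VCF (fixed columns verbatim, GT regenerated
canonically from the four-state codes, so parse→write→parse is the
identity), tab-separated table, and a functional-annotation summary when
the INFO column carries ANNOVAR `Func.*` terms or a snpEff `ANN` field
(first ANN entry = most severe, snpEff's own ordering convention).
Category counts plus the unannotated count always equal the total. VEP
`CSQ` is detected and reported as unsupported; filtering still works.

## Synthetic cohorts

The generator emulates the two study designs: a trio + *n* controls
(default 50) and multi-population cohorts. Background genotypes are drawn
per cell from Hardy-Weinberg proportions at a configurable allele
frequency (default 0.05), with UNKNOWN overlaid at a missing rate (default
0.02); population cohorts draw a separate frequency per variant per
population, uniform with the configured mean. Planted variants overwrite
the trio (and controls) with genotypes that satisfy the target model
exactly; `control_carrier_freq` makes each control independently HET at a
planted site, which is how "common in controls" sites are produced for
MAF-cap experiments. Sites are independent — no linkage disequilibrium, no
realistic site-frequency spectrum, no relatedness beyond the single trio —
so passing tests demonstrate predicate correctness and index fidelity, not
robustness to LD structure or calling artefacts in real data.

## Numerical and testing choices

* Threshold comparisons are plain inclusive float comparisons; MAF and
  percentage values are small-denominator rationals, and the naive-scan
  oracle used in the tests computes them with the same arithmetic, so
  engine/oracle equality is exact.
* The engine-vs-scan equivalence suite runs 50 seeded cohorts of up to
  100 samples × 2,000 variants (alt rate 1–30%, missing 0–10%) across all
  eleven models; planted-recovery experiments use trio + 50 controls ×
  10,000 variants over 20 seeds, with the common-variant leak-through
  compared to its exact binomial expectation within 3σ. These sizes keep
  the whole suite well under a minute while giving every code path
  thousands of random configurations.
* WAH streams are kept canonical (maximal fill runs) by construction and
  after every operation; equality on serialized indexes is word-exact.
* Degenerate inputs: empty VCF bodies index to empty bitmaps; an
  all-UNKNOWN site sorts last (allele count 0); `maf` of a fully uncalled
  site is 0 with an uncalled flag, so a `maf_max` cap passes it and a
  `maf_min` floor rejects it.

## Known limitations

* No BCF or gVCF input; plain or gzip VCF only.
* No byte compatibility with any external index format.
* Compound-het filtering is not phase-aware and not gene-grouped.
* The PED dialect replaces the 6-column linkage format's relationship
  columns with phenotype codes; multi-family PEDs must be split into one
  PED per family/query.
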
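"""Index a small annotated VCF, query it, and summarise the results.

Writes a six-variant annotated VCF inline, builds and saves the
.gqt/.bim/.vid index triple, reloads it, runs the case-specific filter,
and prints the functional-annotation summary plus the per-sample variant
count.
"""

from pathlib import Path
import tempfile

from genoquery import (
    build_index,
    count_variants,
    create_sample_db,
    filter_case_specific,
    format_summary,
    load_index,
    parse_ped,
    read_vcf,
    save_index,
    summarize_annotations,
)

VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcase1\tctrl1\tctrl2
1\t101\t.\tA\tG\t50\tPASS\tFunc.refGene=exonic\tGT\t1/1\t0/0\t0/0
1\t202\t.\tC\tT\t50\tPASS\tFunc.refGene=exonic\tGT\t1/1\t0/0\t0/0
1\t303\t.\tG\tA\t50\tPASS\tFunc.refGene=intronic\tGT\t1/1\t0/0\t0/0
1\t404\t.\tT\tC\t50\tPASS\tFunc.refGene=intronic\tGT\t0/1\t0/1\t0/0
1\t505\t.\tA\tC\t50\tPASS\tFunc.refGene=intergenic\tGT\t1/1\t0/1\t0/0
1\t606\t.\tG\tT\t50\tPASS\tDP=30\tGT\t1/1\t0/0\t0/0
"""

PED = """\
IndividualID\tPhenotype\tSex\tPopulation
case1\t2\t1\tNA
ctrl1\t1\t2\tNA
ctrl2\t1\t1\tNA
"""

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "demo.vcf").write_text(VCF)
    (tmp / "demo.ped").write_text(PED)

    header, records, matrix = read_vcf(tmp / "demo.vcf")
    save_index(build_index(records, matrix), tmp / "demo")
    index = load_index(tmp / "demo")  # the .gqt/.bim/.vid triple
    db = create_sample_db(parse_ped(tmp / "demo.ped"), index)

    result = filter_case_specific(index, db, {"hom_alt"})
    summary = summarize_annotations(result)
    print("case-specific HOM_ALT variants (absent from both controls):")
    print(format_summary(result, summary))
    print()
    n = count_variants(index, db, "case1", {"het_hom_alt"})
    print(f"case1 carries {n} non-reference genotypes out of "
          f"{index.n_variants} variants")
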
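"""Result rendering: VCF / tabular export and functional-annotation summaries.

Filters pass INFO through untouched, so if the input carried annotation
(ANNOVAR-style ``Func.*`` / ``ExonicFunc.*`` keys or a snpEff ``ANN``
field) the surviving variants can be summarised by functional region.
Annotation is optional: unannotated inputs yield an empty summary, never
an error.  VEP ``CSQ`` annotation is detected but not summarised.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .query_models import FilterResult
from .vcf_io import GenotypeMatrix, write_vcf

_TABLE_COLUMNS = (
    "CHROM",
    "POS",
    "ID",
    "REF",
    "ALT",
    "QUAL",
    "FILTER",
    "INFO",
)


@dataclass
class AnnotationSummary:
    dialect: str  # annovar | snpeff | vep-unsupported | none
    counts: dict[str, int] = field(default_factory=dict)
    n_unannotated: int = 0

    @property
    def n_annotated(self) -> int:
        return sum(self.counts.values())


def _info_map(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info in (".", ""):
        return out
    for part in info.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
        else:
            out[part] = ""
    return out


def _annovar_term(info: dict[str, str]) -> str | None:
    # Func.refGene / Func.ensGene etc.; the region term is the value
    for key, value in info.items():
        if key.startswith("Func.") and value:
            return value.replace("\\x3b", ";")
    return None


def _snpeff_term(info: dict[str, str]) -> str | None:
    ann = info.get("ANN")
    if not ann:
        return None
    # first annotation entry = most severe by snpEff convention;
    # ANN format: Allele|Annotation|Impact|...
    first = ann.split(",")[0].split("|")
    return first[1] if len(first) > 1 and first[1] else None


def summarize_annotations(result: FilterResult) -> AnnotationSummary:
    """Count surviving variants per functional category.

    The dialect is auto-detected from INFO keys across the result; counts
    plus ``n_unannotated`` always sum to ``n_total``.
    """
    infos = [_info_map(r.info) for r in result.variants]
    has_annovar = any(
        k.startswith(("Func.", "ExonicFunc.")) for m in infos for k in m
    )
    has_snpeff = any("ANN" in m for m in infos)
    has_vep = any("CSQ" in m for m in infos)

    counts: Counter[str] = Counter()
    if has_annovar:
        dialect = "annovar"
        terms = [_annovar_term(m) for m in infos]
    elif has_snpeff:
        dialect = "snpeff"
        terms = [_snpeff_term(m) for m in infos]
    elif has_vep:
        dialect = "vep-unsupported"
        terms = [None] * len(infos)
    else:
        dialect = "none"
        terms = [None] * len(infos)
    for term in terms:
        if term is not None:
            counts[term] += 1
    n_unannotated = sum(1 for t in terms if t is None)
    return AnnotationSummary(
        dialect=dialect, counts=dict(counts), n_unannotated=n_unannotated
    )


def export_table(result: FilterResult, path: str | Path) -> None:
    """Tab-separated table of the surviving variants (one row each).

    Fields containing a tab, quote, or newline are quoted; an ``.xls``
    path is accepted for spreadsheet users but the content is plain text.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_MINIMAL)
        writer.writerow(_TABLE_COLUMNS)
        for r in result.variants:
            writer.writerow(
                (r.chrom, r.pos, r.id, r.ref, r.alt, r.qual, r.filter, r.info)
            )


def emit_vcf(
    result: FilterResult,
    header: Sequence[str],
    matrix: GenotypeMatrix,
    path: str | Path,
) -> None:
    """Write the surviving variants as a valid VCF in input file order.

    ``matrix`` is the full original-order genotype matrix (from parsing or
    from index reconstruction); rows are selected by original_index.
    """
    write_vcf(header, result.variants, matrix, path)


def format_summary(result: FilterResult, summary: AnnotationSummary) -> str:
    """Human-readable total + per-category table."""
    lines = [f"total variants: {result.n_total}"]
    if result.note:
        lines.append(f"note: {result.note}")
    if summary.counts:
        lines.append(f"functional categories ({summary.dialect}):")
        width = max(len(k) for k in [*summary.counts, "(unannotated)"])
        for term, n in sorted(summary.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {term.ljust(width)}  {n}")
        if summary.n_unannotated:
            lines.append(f"  {'(unannotated)'.ljust(width)}  {summary.n_unannotated}")
    elif summary.dialect == "vep-unsupported":
        lines.append(
            "annotation summary: VEP CSQ annotation detected but not "
            "supported; summary left empty"
        )
    else:
        lines.append("annotation summary: no annotation present")
    return "\n".join(lines)


def write_summary(
    result: FilterResult, summary: AnnotationSummary, path: str | Path
) -> None:
    """Machine-readable summary as a small TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"n_total\t{result.n_total}\n")
        fh.write(f"dialect\t{summary.dialect}\n")
        fh.write(f"n_unannotated\t{summary.n_unannotated}\n")
        for term, n in sorted(summary.counts.items()):
            fh.write(f"category:{term}\t{n}\n")
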
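"""Multi-sample VCF parsing and writing.

Variants are read into raw-string records (the eight fixed columns are kept
verbatim, INFO untouched) plus a V x S matrix of four-state genotype codes:
HOM_REF (no ALT alleles), HET (one), HOM_ALT (two or more), UNKNOWN (any
missing allele).  Writing emits the fixed columns verbatim and regenerates
a canonical GT column from the codes, so parse -> write -> parse is the
identity on (records, matrix).

Plain and gzip-compressed files are accepted; compression is sniffed from
the magic bytes, not the file name.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np


class VcfError(ValueError):
    """Malformed VCF input."""


class GenotypeCode(IntEnum):
    """Per-sample, per-variant genotype state."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    UNKNOWN = 3


#: canonical GT string emitted for each code when writing
_GT_FOR_CODE = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}


@dataclass(frozen=True)
class VariantRecord:
    """One VCF row: the eight fixed columns as raw strings.

    ``original_index`` is the 0-based position of the row in input file
    order; it is dense and unique within one dataset and is what restores
    file order after allele-frequency sorting.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: str
    filter: str
    info: str
    original_index: int

    @property
    def n_alt(self) -> int:
        return 0 if self.alt in (".", "") else self.alt.count(",") + 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def fixed_fields(self) -> str:
        return "\t".join(
            (
                self.chrom,
                str(self.pos),
                self.id,
                self.ref,
                self.alt,
                self.qual,
                self.filter,
                self.info,
            )
        )


@dataclass
class GenotypeMatrix:
    """Genotype codes for all records x all samples (VCF header order)."""

    sample_names: list[str]
    codes: np.ndarray  # V x S uint8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.sample_names):
            raise VcfError(
                f"matrix shape {self.codes.shape} does not match "
                f"{len(self.sample_names)} samples"
            )

    @property
    def n_variants(self) -> int:
        return int(self.codes.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.codes.shape[1])


def encode_genotype(gt: str, n_alt: int) -> GenotypeCode:
    """Map a VCF GT token onto the four-state code.

    The count of non-reference alleles decides the state (0 -> HOM_REF,
    1 -> HET, >=2 -> HOM_ALT, collapsing multi-allelic ALTs); any missing
    allele ('.') makes the call UNKNOWN.  Haploid calls map to
    HOM_REF/HOM_ALT.  '/' and '|' separators are equivalent.
    """
    alleles = gt.replace("|", "/").split("/")
    if not alleles or any(a == "" for a in alleles):
        raise VcfError(f"malformed GT token {gt!r}")
    if any(a == "." for a in alleles):
        return GenotypeCode.UNKNOWN
    try:
        idx = [int(a) for a in alleles]
    except ValueError as exc:
        raise VcfError(f"malformed GT token {gt!r}") from exc
    bad = [a for a in idx if a > n_alt or a < 0]
    if bad:
        raise VcfError(
            f"GT token {gt!r} references allele {bad[0]} but site has "
            f"{n_alt} ALT allele(s)"
        )
    n_nonref = sum(1 for a in idx if a != 0)
    if len(idx) == 1:  # haploid (chrX/chrY males)
        return GenotypeCode.HOM_ALT if n_nonref else GenotypeCode.HOM_REF
    if n_nonref == 0:
        return GenotypeCode.HOM_REF
    if n_nonref == 1:
        return GenotypeCode.HET
    return GenotypeCode.HOM_ALT


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_vcf(
    path: str | Path,
) -> tuple[list[str], list[VariantRecord], GenotypeMatrix]:
    """Parse a multi-sample VCF (plain or gzipped).

    Returns the raw header lines (verbatim, including the #CHROM line),
    the records in file order, and the genotype-code matrix.
    """
    header: list[str] = []
    records: list[VariantRecord] = []
    rows: list[list[int]] = []
    sample_names: list[str] | None = None

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if sample_names is not None:
                    raise VcfError(f"line {lineno}: meta line after #CHROM header")
                header.append(line)
                continue
            if line.startswith("#CHROM"):
                header.append(line)
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise VcfError(
                        f"line {lineno}: #CHROM header has no sample columns"
                    )
                sample_names = cols[9:]
                continue
            if sample_names is None:
                raise VcfError(f"line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_names):
                raise VcfError(
                    f"line {lineno}: expected {9 + len(sample_names)} columns, "
                    f"got {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise VcfError(f"line {lineno}: bad POS {fields[1]!r}") from exc
            if pos < 1 or not fields[3]:
                raise VcfError(f"line {lineno}: invalid POS/REF")
            rec = VariantRecord(
                chrom=fields[0],
                pos=pos,
                id=fields[2],
                ref=fields[3],
                alt=fields[4],
                qual=fields[5],
                filter=fields[6],
                info=fields[7],
                original_index=len(records),
            )
            fmt_keys = fields[8].split(":")
            try:
                gt_at = fmt_keys.index("GT")
            except ValueError as exc:
                raise VcfError(
                    f"record {rec.chrom}:{rec.pos} has no GT key in FORMAT"
                ) from exc
            row: list[int] = []
            for name, cell in zip(sample_names, fields[9:]):
                parts = cell.split(":")
                if gt_at >= len(parts):
                    raise VcfError(
                        f"record {rec.chrom}:{rec.pos} sample {name}: "
                        f"missing GT value"
                    )
                try:
                    row.append(int(encode_genotype(parts[gt_at], rec.n_alt)))
                except VcfError as exc:
                    raise VcfError(
                        f"record {rec.chrom}:{rec.pos} sample {name}: {exc}"
                    ) from exc
            records.append(rec)
            rows.append(row)

    if sample_names is None:
        raise VcfError(f"{path}: no #CHROM header line found")
    codes = (
        np.asarray(rows, dtype=np.uint8)
        if rows
        else np.empty((0, len(sample_names)), dtype=np.uint8)
    )
    return header, records, GenotypeMatrix(sample_names, codes)


def write_vcf(
    header: Sequence[str],
    records: Sequence[VariantRecord],
    matrix: GenotypeMatrix,
    path: str | Path,
    row_indices: Sequence[int] | None = None,
) -> None:
    """Write records (sorted by original_index) plus canonical GT columns.

    ``row_indices`` gives each record's row in ``matrix``; by default
    record i uses matrix row ``records[i].original_index`` — the usual
    case of emitting a filtered subset against the full input matrix.
    """
    if row_indices is None:
        row_indices = [r.original_index for r in records]
    if len(row_indices) != len(records):
        raise VcfError("row_indices length does not match records")
    last = -1
    for rec in records:
        if rec.original_index <= last:
            raise VcfError("records must be sorted by original_index")
        last = rec.original_index
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header:
                fh.write(line + "\n")
            for rec, row in zip(records, row_indices):
                gts = "\t".join(
                    _GT_FOR_CODE[int(c)] for c in matrix.codes[row]
                )
                fh.write(f"{rec.fixed_fields()}\tGT\t{gts}\n")
    except OSError as exc:
        raise VcfError(f"cannot write VCF to {path}: {exc}") from exc


def minimal_header(sample_names: Sequence[str], contig: str | None = None) -> list[str]:
    """A small valid header for generated cohorts."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contig is not None:
        lines.append(f"##contig=<ID={contig}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    return lines
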
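"""Sample-centric, allele-frequency-sorted, WAH-compressed genotype index.

The variant-centric genotype matrix is transposed so each row is one
individual across all loci, sorted by descending non-reference allele
count (which groups rare sites together and lengthens the runs the WAH
coder can exploit), and stored as four class bitmaps per sample — one per
genotype state.  For every sorted position exactly one of a sample's four
bitmaps is set (the partition property), so the build is lossless.

The index persists as three files sharing a path prefix:

``<prefix>.gqt``
    the compressed per-sample class bitmaps (binary, little-endian words),
``<prefix>.bim``
    the variant metadata in sorted order (gzip-compressed TSV),
``<prefix>.vid``
    the permutation mapping sorted position back to input file order.

The layout is this package's own versioned format; each file opens with a
magic string so mismatched or foreign files are rejected early.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._wah import WahVector, compress, decompress, wah_or
from .vcf_io import GenotypeCode, GenotypeMatrix, VariantRecord

_GQT_MAGIC = b"GQXI"
_VID_MAGIC = b"GQXV"
_BIM_MAGIC = "#GQXB"
_FORMAT_VERSION = 1

_N_CLASSES = 4


class IndexError_(ValueError):
    """Index build, lookup, or file-format failure."""


def sort_by_allele_frequency(
    records: Sequence[VariantRecord], matrix: GenotypeMatrix
) -> tuple[np.ndarray, list[VariantRecord], np.ndarray]:
    """Order variants by descending non-reference allele count.

    UNKNOWN genotypes contribute nothing to the count; ties keep input
    order.  Returns (order_map, sorted records, sorted codes) where
    ``order_map[sorted_pos]`` is the variant's original index.
    """
    codes = matrix.codes
    if codes.shape[0] == 0:
        return (
            np.empty(0, dtype=np.int64),
            [],
            codes.copy(),
        )
    alt_counts = (codes == GenotypeCode.HET).sum(axis=1) + 2 * (
        codes == GenotypeCode.HOM_ALT
    ).sum(axis=1)
    # stable sort on negated counts == descending with original-order ties
    order = np.argsort(-alt_counts, kind="stable").astype(np.int64)
    sorted_records = [records[i] for i in order]
    return order, sorted_records, codes[order]


@dataclass
class SampleBitmapSet:
    """One sample's four class bitmaps over the sorted variant axis."""

    sample_name: str
    class_bitmaps: dict[GenotypeCode, WahVector]

    def state_vector(self, states: Iterable[GenotypeCode]) -> WahVector:
        states = list(states)
        if not states:
            raise IndexError_("states must be nonempty")
        acc = self.class_bitmaps[GenotypeCode(states[0])]
        for s in states[1:]:
            acc = wah_or(acc, self.class_bitmaps[GenotypeCode(s)])
        return acc


@dataclass
class GenotypeIndex:
    """The three-part index: bitmaps, sorted variant metadata, order map."""

    bitmaps: list[SampleBitmapSet]
    variant_meta: list[VariantRecord]
    order_map: np.ndarray  # sorted position -> original_index
    n_variants: int
    n_samples: int
    _sample_pos: dict[str, int] = field(default_factory=dict, repr=False)
    _state_cache: dict[tuple[str, frozenset], np.ndarray] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.order_map = np.asarray(self.order_map, dtype=np.int64)
        if not self._sample_pos:
            self._sample_pos = {b.sample_name: i for i, b in enumerate(self.bitmaps)}

    @property
    def sample_names(self) -> list[str]:
        return [b.sample_name for b in self.bitmaps]

    def sample_position(self, name: str) -> int:
        try:
            return self._sample_pos[name]
        except KeyError:
            raise IndexError_(f"sample {name!r} not in index") from None

    def state_bitmap(
        self, sample: str, states: Iterable[GenotypeCode]
    ) -> WahVector:
        """OR of a sample's class bitmaps over the requested states."""
        return self.bitmaps[self.sample_position(sample)].state_vector(states)

    def state_bits(self, sample: str, states: Iterable[GenotypeCode]) -> np.ndarray:
        """Decompressed boolean vector for ``state_bitmap`` (memoised)."""
        key = (sample, frozenset(int(s) for s in states))
        hit = self._state_cache.get(key)
        if hit is None:
            hit = decompress(self.state_bitmap(sample, states)).astype(bool)
            self._state_cache[key] = hit
        return hit

    def codes_for(self, sample: str) -> np.ndarray:
        """A sample's genotype codes over the sorted variant axis."""
        pos = self.sample_position(sample)
        out = np.zeros(self.n_variants, dtype=np.uint8)
        for code in (GenotypeCode.HET, GenotypeCode.HOM_ALT, GenotypeCode.UNKNOWN):
            bits = decompress(self.bitmaps[pos].class_bitmaps[code])
            out[bits.astype(bool)] = int(code)
        return out

    def original_order(self, sorted_values: np.ndarray) -> np.ndarray:
        """Permute a sorted-axis vector back to input file order."""
        out = np.empty_like(sorted_values)
        out[self.order_map] = sorted_values
        return out


def build_index(
    records: Sequence[VariantRecord], matrix: GenotypeMatrix
) -> GenotypeIndex:
    """Build the AF-sorted, per-sample, 4-class WAH index from a parsed VCF."""
    order_map, sorted_records, sorted_codes = sort_by_allele_frequency(
        records, matrix
    )
    bitmaps: list[SampleBitmapSet] = []
    for s, name in enumerate(matrix.sample_names):
        col = sorted_codes[:, s] if sorted_codes.size else sorted_codes.reshape(-1)
        class_bitmaps = {
            code: compress((col == int(code)).astype(np.uint8))
            for code in GenotypeCode
        }
        bitmaps.append(SampleBitmapSet(name, class_bitmaps))
    return GenotypeIndex(
        bitmaps=bitmaps,
        variant_meta=sorted_records,
        order_map=order_map,
        n_variants=matrix.n_variants,
        n_samples=matrix.n_samples,
    )


def reconstruct_matrix(index: GenotypeIndex) -> GenotypeMatrix:
    """Invert the index back to the original-order genotype matrix."""
    codes_sorted = np.zeros((index.n_variants, index.n_samples), dtype=np.uint8)
    for s, name in enumerate(index.sample_names):
        codes_sorted[:, s] = index.codes_for(name)
    codes = np.empty_like(codes_sorted)
    codes[index.order_map] = codes_sorted
    return GenotypeMatrix(list(index.sample_names), codes)


# ---------------------------------------------------------------------------
# serialization


def _index_paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    base = str(prefix)
    return (Path(base + ".gqt"), Path(base + ".bim"), Path(base + ".vid"))


def save_index(index: GenotypeIndex, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write the .gqt/.bim/.vid triple; returns the three paths."""
    gqt, bim, vid = _index_paths(prefix)

    with open(gqt, "wb") as fh:
        fh.write(_GQT_MAGIC)
        fh.write(struct.pack("<HII", _FORMAT_VERSION, index.n_samples, index.n_variants))
        for bset in index.bitmaps:
            name = bset.sample_name.encode("utf-8")
            fh.write(struct.pack("<H", len(name)))
            fh.write(name)
            for code in GenotypeCode:
                vec = bset.class_bitmaps[code]
                fh.write(struct.pack("<II", vec.logical_length, vec.n_words))
                fh.write(vec.words.astype("<u4").tobytes())

    with gzip.open(bim, "wt", encoding="utf-8") as th:
        th.write(f"{_BIM_MAGIC}\t{_FORMAT_VERSION}\n")
        for rec in index.variant_meta:
            th.write(
                "\t".join(
                    (
                        rec.chrom,
                        str(rec.pos),
                        rec.id,
                        rec.ref,
                        rec.alt,
                        rec.qual,
                        rec.filter,
                        rec.info,
                        str(rec.original_index),
                    )
                )
                + "\n"
            )

    with open(vid, "wb") as fh:
        fh.write(_VID_MAGIC)
        fh.write(struct.pack("<HI", _FORMAT_VERSION, index.n_variants))
        fh.write(index.order_map.astype("<u4").tobytes())

    return gqt, bim, vid


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise IndexError_(f"truncated index file while reading {what}")
    return buf


def load_index(prefix: str | Path) -> GenotypeIndex:
    """Load an index written by :func:`save_index`."""
    gqt, bim, vid = _index_paths(prefix)
    missing = [p.name for p in (gqt, bim, vid) if not p.exists()]
    if missing:
        raise IndexError_(f"missing index component(s): {', '.join(missing)}")

    with open(gqt, "rb") as fh:
        if _read_exact(fh, 4, "magic") != _GQT_MAGIC:
            raise IndexError_(f"{gqt}: not an index file")
        version, n_samples, n_variants = struct.unpack(
            "<HII", _read_exact(fh, 10, "header")
        )
        if version != _FORMAT_VERSION:
            raise IndexError_(
                f"{gqt}: format version {version} not supported "
                f"(expected {_FORMAT_VERSION})"
            )
        bitmaps: list[SampleBitmapSet] = []
        for _ in range(n_samples):
            (name_len,) = struct.unpack("<H", _read_exact(fh, 2, "sample name"))
            name = _read_exact(fh, name_len, "sample name").decode("utf-8")
            class_bitmaps: dict[GenotypeCode, WahVector] = {}
            for code in GenotypeCode:
                length, n_words = struct.unpack(
                    "<II", _read_exact(fh, 8, "bitmap header")
                )
                raw = _read_exact(fh, 4 * n_words, "bitmap words")
                words = np.frombuffer(raw, dtype="<u4").astype(np.uint32)
                class_bitmaps[code] = WahVector(words, length)
            bitmaps.append(SampleBitmapSet(name, class_bitmaps))

    variant_meta: list[VariantRecord] = []
    with gzip.open(bim, "rt", encoding="utf-8") as th:
        first = th.readline().rstrip("\n").split("\t")
        if not first or first[0] != _BIM_MAGIC:
            raise IndexError_(f"{bim}: not an index file")
        if int(first[1]) != _FORMAT_VERSION:
            raise IndexError_(f"{bim}: format version {first[1]} not supported")
        for line in th:
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise IndexError_(f"{bim}: malformed metadata row")
            variant_meta.append(
                VariantRecord(
                    chrom=f[0],
                    pos=int(f[1]),
                    id=f[2],
                    ref=f[3],
                    alt=f[4],
                    qual=f[5],
                    filter=f[6],
                    info=f[7],
                    original_index=int(f[8]),
                )
            )

    with open(vid, "rb") as fh:
        if _read_exact(fh, 4, "magic") != _VID_MAGIC:
            raise IndexError_(f"{vid}: not an index file")
        version, n = struct.unpack("<HI", _read_exact(fh, 6, "header"))
        if version != _FORMAT_VERSION:
            raise IndexError_(f"{vid}: format version {version} not supported")
        raw = _read_exact(fh, 4 * n, "order map")
        order_map = np.frombuffer(raw, dtype="<u4").astype(np.int64)

    if len(variant_meta) != n_variants or order_map.size != n_variants:
        raise IndexError_("index components disagree on variant count")
    return GenotypeIndex(
        bitmaps=bitmaps,
        variant_meta=variant_meta,
        order_map=order_map,
        n_variants=n_variants,
        n_samples=n_samples,
    )
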
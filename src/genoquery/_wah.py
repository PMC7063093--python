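"""Word-Aligned Hybrid (WAH) compressed bit vectors.

A WAH vector stores a bit stream as a sequence of 32-bit words.  Each word
is either a *literal* holding 31 payload bits (most significant bit 0) or a
*fill* encoding a run of identical all-zero or all-one 31-bit groups
(MSB 1, next bit the fill value, low 30 bits the run length in groups).
Boolean algebra (AND/OR/NOT) operates run-wise on the compressed form, so a
fill of a million groups is consumed in one step rather than being expanded.

The logical length is carried separately; the final group is zero-padded on
compression and the padding is discarded on decompression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WORD_WIDTH = 32
PAYLOAD = WORD_WIDTH - 1  # 31 payload bits per group
FILL_FLAG = np.uint32(1 << 31)
FILL_BIT = np.uint32(1 << 30)
MAX_RUN = (1 << 30) - 1
ALL_ONES = np.uint32((1 << PAYLOAD) - 1)

_POWERS = (np.uint32(1) << np.arange(PAYLOAD - 1, -1, -1, dtype=np.uint32)).astype(
    np.uint32
)


class WahError(ValueError):
    """Malformed WAH stream or incompatible operands."""


@dataclass
class WahVector:
    """A WAH-compressed bit vector.

    Attributes
    ----------
    words : np.ndarray
        uint32 word stream (literals and fills).
    logical_length : int
        Number of bits the vector represents.
    """

    words: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint32))
    logical_length: int = 0

    def __post_init__(self) -> None:
        self.words = np.asarray(self.words, dtype=np.uint32)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WahVector):
            return NotImplemented
        return self.logical_length == other.logical_length and np.array_equal(
            self.words, other.words
        )

    def __len__(self) -> int:
        return self.logical_length

    @property
    def n_words(self) -> int:
        return int(self.words.size)

    def popcount(self) -> int:
        """Number of set bits.

        Assumes canonical zero padding in the final partial group, which
        holds for compress() output and for AND/OR of canonical vectors.
        """
        if self.words.size == 0:
            return 0
        is_fill = (self.words & FILL_FLAG) != 0
        lits = self.words[~is_fill]
        total = int(np.bitwise_count(lits).sum()) if lits.size else 0
        ones = self.words[is_fill & ((self.words & FILL_BIT) != 0)]
        if ones.size:
            total += PAYLOAD * int((ones & np.uint32(MAX_RUN)).astype(np.int64).sum())
        return total


def _runs(words: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decode a word stream into (group_value, group_count) run arrays."""
    if words.size == 0:
        return np.empty(0, dtype=np.uint32), np.empty(0, dtype=np.int64)
    is_fill = (words & FILL_FLAG) != 0
    values = np.where(
        is_fill,
        np.where((words & FILL_BIT) != 0, ALL_ONES, np.uint32(0)),
        words,
    ).astype(np.uint32)
    counts = np.where(is_fill, (words & np.uint32(MAX_RUN)).astype(np.int64), 1)
    if is_fill.any() and (counts[is_fill] == 0).any():
        raise WahError("fill word with zero run length")
    return values, counts


def _encode_groups(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Re-encode (value, count) runs into a canonical word stream.

    Adjacent runs of the same fillable value are coalesced so no two
    neighbouring fill words share a fill bit (maximal runs).
    """
    words: list[int] = []
    pend_val = -1  # fill value of pending run: 0 or 1, -1 none
    pend_n = 0

    def flush() -> None:
        nonlocal pend_n
        n = pend_n
        while n > 0:
            take = min(n, MAX_RUN)
            words.append(
                int(FILL_FLAG) | (int(FILL_BIT) if pend_val else 0) | take
            )
            n -= take
        pend_n = 0

    for v, c in zip(values.tolist(), counts.tolist()):
        if v == 0 or v == int(ALL_ONES):
            bit = 0 if v == 0 else 1
            if pend_n and pend_val == bit:
                pend_n += c
            else:
                if pend_n:
                    flush()
                pend_val, pend_n = bit, c
        else:
            if pend_n:
                flush()
            words.extend([v] * c)
    if pend_n:
        flush()
    return np.asarray(words, dtype=np.uint32)


def compress(bits: np.ndarray) -> WahVector:
    """Compress a 0/1 bit array into a canonical WAH vector."""
    bits = np.asarray(bits, dtype=np.uint8)
    n = bits.size
    if n == 0:
        return WahVector(np.empty(0, dtype=np.uint32), 0)
    n_groups = -(-n // PAYLOAD)
    padded = np.zeros(n_groups * PAYLOAD, dtype=np.uint32)
    padded[:n] = bits
    groups = (padded.reshape(n_groups, PAYLOAD) * _POWERS).sum(axis=1).astype(np.uint32)

    # run-length encode the group stream
    if n_groups == 1:
        values, counts = groups, np.ones(1, dtype=np.int64)
    else:
        change = np.flatnonzero(groups[1:] != groups[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n_groups]))
        values, counts = groups[starts], (ends - starts).astype(np.int64)
    return WahVector(_encode_groups(values, counts), n)


def decompress(vec: WahVector) -> np.ndarray:
    """Expand a WAH vector back into its 0/1 bit array (uint8)."""
    values, counts = _runs(vec.words)
    n_groups = int(counts.sum())
    need = -(-vec.logical_length // PAYLOAD)
    if n_groups != need:
        raise WahError(
            f"truncated or overlong stream: {n_groups} groups for "
            f"{vec.logical_length} bits"
        )
    if n_groups == 0:
        return np.empty(0, dtype=np.uint8)
    groups = np.repeat(values, counts)
    bits = ((groups[:, None] >> np.arange(PAYLOAD - 1, -1, -1)) & 1).astype(np.uint8)
    return bits.reshape(-1)[: vec.logical_length]


def _binary_op(a: WahVector, b: WahVector, op: str) -> WahVector:
    if a.logical_length != b.logical_length:
        raise WahError(
            f"length mismatch: {a.logical_length} vs {b.logical_length}"
        )
    av, ac = _runs(a.words)
    bv, bc = _runs(b.words)
    out_v: list[int] = []
    out_c: list[int] = []
    i = j = 0
    ra = int(ac[0]) if ac.size else 0
    rb = int(bc[0]) if bc.size else 0
    while i < av.size and j < bv.size:
        take = min(ra, rb)
        if op == "and":
            v = int(av[i]) & int(bv[j])
        else:
            v = int(av[i]) | int(bv[j])
        if out_c and out_v[-1] == v:
            out_c[-1] += take
        else:
            out_v.append(v)
            out_c.append(take)
        ra -= take
        rb -= take
        if ra == 0:
            i += 1
            if i < av.size:
                ra = int(ac[i])
        if rb == 0:
            j += 1
            if j < bv.size:
                rb = int(bc[j])
    if (i < av.size) != (j < bv.size):
        raise WahError("operand streams disagree on group count")
    words = _encode_groups(
        np.asarray(out_v, dtype=np.uint32), np.asarray(out_c, dtype=np.int64)
    )
    return WahVector(words, a.logical_length)


def wah_and(a: WahVector, b: WahVector) -> WahVector:
    """Bitwise AND of two compressed vectors, computed run-wise."""
    return _binary_op(a, b, "and")


def wah_or(a: WahVector, b: WahVector) -> WahVector:
    """Bitwise OR of two compressed vectors, computed run-wise."""
    return _binary_op(a, b, "or")


def wah_not(a: WahVector) -> WahVector:
    """Bitwise complement.

    Padding bits in the final partial group become 1; decompress truncates
    them, so the logical content is the exact complement.
    """
    values, counts = _runs(a.words)
    values = (~values) & ALL_ONES
    return WahVector(_encode_groups(values, counts), a.logical_length)


def all_zeros(length: int) -> WahVector:
    return compress(np.zeros(length, dtype=np.uint8))


def all_ones(length: int) -> WahVector:
    return compress(np.ones(length, dtype=np.uint8))
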
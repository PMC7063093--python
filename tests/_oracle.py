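"""Naive variant-centric scan oracle.

Re-implements every filter predicate by looping over matrix rows in input
order, without touching the bitmap index, allele-frequency sorting, or any
compressed representation.  Genotype codes: 0 HOM_REF, 1 HET, 2 HOM_ALT,
3 UNKNOWN.  Used to check that the index-backed engine returns exactly the
same variant sets.
"""

from __future__ import annotations

HOM_REF, HET, HOM_ALT, UNKNOWN = 0, 1, 2, 3


def row_maf(row, cols):
    """(value, uncalled) for one variant over the given sample columns."""
    n_het = sum(1 for c in cols if row[c] == HET)
    n_hom = sum(1 for c in cols if row[c] == HOM_ALT)
    n_called = sum(1 for c in cols if row[c] != UNKNOWN)
    if n_called == 0:
        return 0.0, True
    return (n_het + 2 * n_hom) / (2 * n_called), False


def row_count(row, cols, states):
    return sum(1 for c in cols if row[c] in states)


def _all_in(row, cols, states):
    return all(row[c] in states for c in cols)


def _case_states(base, allow_missing):
    return {base, UNKNOWN} if allow_missing else {base}


def _maf_ok(row, controls, maf_max):
    if maf_max is None or not controls:
        return True
    value, _ = row_maf(row, controls)
    return value <= maf_max


def scan_recessive(codes, parents, cases, controls, maf_max=None, allow_missing=False):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        if not _all_in(row, parents, {HET}):
            continue
        if not _all_in(row, cases, _case_states(HOM_ALT, allow_missing)):
            continue
        if not _maf_ok(row, controls, maf_max):
            continue
        out.add(v)
    return out


def scan_compound_het(
    codes, parents, cases, controls, maf_max=None, allow_missing=False
):
    assert len(parents) == 2
    p1, p2 = parents
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        one_carrier = (row[p1] == HET and row[p2] == HOM_REF) or (
            row[p2] == HET and row[p1] == HOM_REF
        )
        if not one_carrier:
            continue
        if not _all_in(row, cases, _case_states(HET, allow_missing)):
            continue
        if not _maf_ok(row, controls, maf_max):
            continue
        out.add(v)
    return out if len(out) >= 2 else set()


def scan_dominant(codes, parents, cases, controls, maf_max=None, allow_missing=False):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        if not _all_in(row, parents, {HET}):
            continue
        if not _all_in(row, cases, _case_states(HET, allow_missing)):
            continue
        if not _maf_ok(row, controls, maf_max):
            continue
        out.add(v)
    return out


def scan_recessive_denovo(
    codes, parents, cases, controls, maf_max=None, allow_missing=False
):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        if not _all_in(row, parents, {HOM_REF}):
            continue
        if not _all_in(row, cases, _case_states(HOM_ALT, allow_missing)):
            continue
        if not _maf_ok(row, controls, maf_max):
            continue
        out.add(v)
    return out


def scan_dominant_denovo(codes, parents, cases, allow_missing=False):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        if not _all_in(row, parents, {HOM_REF}):
            continue
        if not _all_in(row, cases, _case_states(HET, allow_missing)):
            continue
        out.add(v)
    return out


def scan_case_specific(codes, cases, controls, states, allow_missing_controls=False):
    control_states = {HOM_REF, UNKNOWN} if allow_missing_controls else {HOM_REF}
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        if not _all_in(row, cases, set(states)):
            continue
        if not _all_in(row, controls, control_states):
            continue
        out.add(v)
    return out


def scan_cases_shared(codes, cases, controls, states, maf_max=None):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        if not _all_in(row, cases, set(states)):
            continue
        if not _maf_ok(row, controls, maf_max):
            continue
        out.add(v)
    return out


def scan_pop_allele_freq(codes, cols_a, cols_b, maf_min_a, maf_max_b):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        value_a, _ = row_maf(row, cols_a)
        value_b, _ = row_maf(row, cols_b)
        if value_a >= maf_min_a and value_b <= maf_max_b:
            out.add(v)
    return out


def scan_pop_individual_count(codes, cols_a, cols_b, state, pct_min_a, pct_max_b):
    out = set()
    for v in range(codes.shape[0]):
        row = codes[v]
        frac_a = row_count(row, cols_a, {state}) / len(cols_a)
        frac_b = row_count(row, cols_b, {state}) / len(cols_b)
        if frac_a >= pct_min_a / 100.0 and frac_b <= pct_max_b / 100.0:
            out.add(v)
    return out


def scan_by_sample(codes, cols, states, count_min):
    return {
        v
        for v in range(codes.shape[0])
        if row_count(codes[v], cols, set(states)) >= count_min
    }


def scan_variant_count(codes, col, states):
    return sum(1 for v in range(codes.shape[0]) if codes[v, col] in set(states))
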
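"""Model-based variant filters over the WAH genotype index.

Eleven filters grouped the way a geneticist frames the study:

* pedigree — recessive, compound heterozygous, dominant, recessive de
  novo, dominant de novo (carrier/affected parents coded Phenotype=3,
  affected offspring Phenotype=2);
* case-control — case-specific, cases-shared (cases Phenotype=2 against
  unaffected controls Phenotype=1);
* population — allele-frequency and individual-count comparisons between
  two populations, plus sample-restricted retrieval and a per-sample
  variant counter.

Two cross-cutting parameters: a control-cohort MAF cutoff (fraction) that
drops variants common among Phenotype=1 samples, and missing-genotype
rescue, which lets UNKNOWN calls in *affected* samples satisfy the
required state (parents and controls are never rescued; the case-specific
model has its own explicit control-missing flag and cases-shared may list
UNKNOWN as an accepted state).

Threshold comparisons are inclusive (>= minima, <= maxima); percentage
thresholds are given in percent (0-100) and compared as fractions, MAF
thresholds as fractions in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._wah import decompress, wah_and, wah_or
from .sample_db import SampleDB
from .vcf_io import GenotypeCode, VariantRecord
from .wah_index import GenotypeIndex

logger = logging.getLogger(__name__)

PEDIGREE_MODELS = (
    "recessive",
    "compound_het",
    "dominant",
    "recessive_denovo",
    "dominant_denovo",
)
ALL_MODELS = PEDIGREE_MODELS + (
    "case_specific",
    "cases_shared",
    "pop_allele_freq",
    "pop_individual_count",
    "by_sample",
    "variant_count",
)

_STATE_ALIASES = {
    "hom_ref": GenotypeCode.HOM_REF,
    "het": GenotypeCode.HET,
    "hom_alt": GenotypeCode.HOM_ALT,
    "unknown": GenotypeCode.UNKNOWN,
}


class ModelError(ValueError):
    """Invalid model parameters or sample configuration."""


def normalize_states(states: Iterable[object]) -> frozenset[GenotypeCode]:
    out = set()
    for s in states:
        if isinstance(s, GenotypeCode):
            out.add(s)
        elif isinstance(s, int):
            out.add(GenotypeCode(s))
        else:
            key = str(s).strip().lower().replace("-", "_")
            if key == "het_hom_alt":
                out.update((GenotypeCode.HET, GenotypeCode.HOM_ALT))
            elif key in _STATE_ALIASES:
                out.add(_STATE_ALIASES[key])
            else:
                raise ModelError(f"unknown genotype state {s!r}")
    if not out:
        raise ModelError("states must be nonempty")
    return frozenset(out)


@dataclass
class FilterResult:
    """Surviving variants restored to input file order, plus provenance."""

    variants: list[VariantRecord]
    model: str
    params: dict = field(default_factory=dict)
    note: str | None = None

    @property
    def n_total(self) -> int:
        return len(self.variants)

    @property
    def original_indices(self) -> list[int]:
        return [r.original_index for r in self.variants]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.variants}


# ---------------------------------------------------------------------------
# per-variant primitives (all return vectors in original input order)


def _require_samples(samples: Sequence[str], what: str) -> None:
    if not samples:
        raise ModelError(f"no samples selected for {what}")


def count(
    index: GenotypeIndex,
    samples: Sequence[str],
    states: Iterable[object],
) -> np.ndarray:
    """Per-variant number of the given samples whose code is in ``states``."""
    _require_samples(samples, "count")
    states = normalize_states(states)
    acc = np.zeros(index.n_variants, dtype=np.int64)
    for name in samples:
        acc += index.state_bits(name, states)
    return index.original_order(acc)


def pct(
    index: GenotypeIndex,
    samples: Sequence[str],
    states: Iterable[object],
) -> np.ndarray:
    """count / number of selected samples (UNKNOWN carriers stay in the
    denominator)."""
    return count(index, samples, states) / len(samples)


def maf(
    index: GenotypeIndex, samples: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency over called genotypes.

    Returns (values, uncalled): value = (n_HET + 2 * n_HOM_ALT) /
    (2 * n_called); where every selected sample is UNKNOWN the value is 0
    and the uncalled flag is set.
    """
    _require_samples(samples, "maf")
    n_het = np.zeros(index.n_variants, dtype=np.int64)
    n_hom = np.zeros(index.n_variants, dtype=np.int64)
    n_unk = np.zeros(index.n_variants, dtype=np.int64)
    for name in samples:
        n_het += index.state_bits(name, {GenotypeCode.HET})
        n_hom += index.state_bits(name, {GenotypeCode.HOM_ALT})
        n_unk += index.state_bits(name, {GenotypeCode.UNKNOWN})
    n_called = len(samples) - n_unk
    uncalled = n_called == 0
    vals = np.zeros(index.n_variants, dtype=np.float64)
    ok = ~uncalled
    vals[ok] = (n_het[ok] + 2 * n_hom[ok]) / (2 * n_called[ok])
    return index.original_order(vals), index.original_order(uncalled)


# ---------------------------------------------------------------------------
# shared machinery for the filter models


def _groups(db: SampleDB) -> tuple[list[str], list[str], list[str]]:
    if not db.has_phenotype:
        raise ModelError(
            "sample database has no Phenotype column; pedigree and "
            "case-control models need one"
        )
    return (
        db.select(phenotype={3}),
        db.select(phenotype={2}),
        db.select(phenotype={1}),
    )


def _all_in_states(
    index: GenotypeIndex,
    samples: Sequence[str],
    states: frozenset[GenotypeCode],
) -> np.ndarray:
    """Sorted-order boolean: every sample's code is in ``states``.

    The conjunction is taken in the compressed domain (run-wise AND of the
    samples' state bitmaps) and decompressed once.
    """
    acc = index.state_bitmap(samples[0], states)
    for name in samples[1:]:
        acc = wah_and(acc, index.state_bitmap(name, states))
    return decompress(acc).astype(bool)


def _case_states(base: GenotypeCode, allow_missing: bool) -> frozenset[GenotypeCode]:
    states = {base}
    if allow_missing:
        states.add(GenotypeCode.UNKNOWN)
    return frozenset(states)


def _control_maf_mask(
    index: GenotypeIndex, db: SampleDB, maf_max: float | None
) -> np.ndarray | None:
    """Sorted-order mask for maf(controls) <= maf_max, or None to no-op."""
    if maf_max is None:
        return None
    controls = db.select(phenotype={1})
    if not controls:
        logger.warning(
            "control MAF cutoff requested but no Phenotype=1 samples exist; "
            "the cutoff is ignored"
        )
        return None
    vals, _ = maf(index, controls)  # original order
    mask_orig = vals <= maf_max
    return mask_orig[index.order_map]  # back to sorted order


def _result(
    index: GenotypeIndex,
    mask_sorted: np.ndarray,
    model: str,
    params: dict,
    note: str | None = None,
) -> FilterResult:
    variants = [index.variant_meta[i] for i in np.flatnonzero(mask_sorted)]
    variants.sort(key=lambda r: r.original_index)
    return FilterResult(variants=variants, model=model, params=params, note=note)


def _require_trio_groups(
    parents: Sequence[str], cases: Sequence[str], model: str
) -> None:
    if not parents and not cases:
        raise ModelError(
            f"{model}: no Phenotype=3 parents and no Phenotype=2 cases in "
            "the database; for case-only data use the case-control module"
        )
    if not parents:
        raise ModelError(
            f"{model}: no Phenotype=3 parent/carrier samples; without "
            "parental genotypes switch to the case-specific module"
        )
    if not cases:
        raise ModelError(f"{model}: no Phenotype=2 affected samples")


# ---------------------------------------------------------------------------
# pedigree module


def filter_recessive(
    index: GenotypeIndex,
    db: SampleDB,
    maf_max: float | None = None,
    allow_missing: bool = False,
) -> FilterResult:
    """Recessive inheritance: carrier parents HET, affected HOM_ALT.

    UNKNOWN in affected samples is accepted under ``allow_missing``;
    ``maf_max`` caps the control-cohort MAF.
    """
    parents, cases, _ = _groups(db)
    _require_trio_groups(parents, cases, "recessive")
    mask = _all_in_states(index, parents, frozenset({GenotypeCode.HET}))
    mask &= _all_in_states(
        index, cases, _case_states(GenotypeCode.HOM_ALT, allow_missing)
    )
    cap = _control_maf_mask(index, db, maf_max)
    if cap is not None:
        mask &= cap
    return _result(
        index,
        mask,
        "recessive",
        {"maf_max": maf_max, "allow_missing": allow_missing},
    )


def filter_compound_het(
    index: GenotypeIndex,
    db: SampleDB,
    maf_max: float | None = None,
    allow_missing: bool = False,
) -> FilterResult:
    """Compound heterozygous candidates, single-variant level.

    A candidate has every affected sample HET while exactly one of the two
    parents is HET and the other is wild type (HOM_REF).  At least two
    candidates must survive — one variant cannot be compound — otherwise
    the result is empty with an explanatory note.
    """
    parents, cases, _ = _groups(db)
    if len(parents) != 2:
        raise ModelError(
            f"compound_het: exactly 2 Phenotype=3 parents required, "
            f"found {len(parents)}; the trio needs both parental genotypes"
        )
    if not cases:
        raise ModelError("compound_het: no Phenotype=2 affected samples")
    p1, p2 = parents
    het = frozenset({GenotypeCode.HET})
    wt = frozenset({GenotypeCode.HOM_REF})
    from_p1 = _all_in_states(index, [p1], het) & _all_in_states(index, [p2], wt)
    from_p2 = _all_in_states(index, [p2], het) & _all_in_states(index, [p1], wt)
    mask = (from_p1 | from_p2) & _all_in_states(
        index, cases, _case_states(GenotypeCode.HET, allow_missing)
    )
    cap = _control_maf_mask(index, db, maf_max)
    if cap is not None:
        mask &= cap
    params = {"maf_max": maf_max, "allow_missing": allow_missing}
    if int(mask.sum()) < 2:
        return _result(
            index,
            np.zeros_like(mask),
            "compound_het",
            params,
            note="fewer than two candidates; a compound-heterozygous "
            "genotype needs at least two variants",
        )
    return _result(index, mask, "compound_het", params)


def filter_dominant(
    index: GenotypeIndex,
    db: SampleDB,
    maf_max: float | None = None,
    allow_missing: bool = False,
) -> FilterResult:
    """Dominant inheritance: affected parent(s) and affected offspring HET."""
    parents, cases, _ = _groups(db)
    _require_trio_groups(parents, cases, "dominant")
    mask = _all_in_states(index, parents, frozenset({GenotypeCode.HET}))
    mask &= _all_in_states(
        index, cases, _case_states(GenotypeCode.HET, allow_missing)
    )
    cap = _control_maf_mask(index, db, maf_max)
    if cap is not None:
        mask &= cap
    return _result(
        index,
        mask,
        "dominant",
        {"maf_max": maf_max, "allow_missing": allow_missing},
    )


def filter_recessive_denovo(
    index: GenotypeIndex,
    db: SampleDB,
    maf_max: float | None = None,
    allow_missing: bool = False,
) -> FilterResult:
    """Novel homozygous mutations: parents HOM_REF, affected HOM_ALT."""
    parents, cases, _ = _groups(db)
    _require_trio_groups(parents, cases, "recessive_denovo")
    mask = _all_in_states(index, parents, frozenset({GenotypeCode.HOM_REF}))
    mask &= _all_in_states(
        index, cases, _case_states(GenotypeCode.HOM_ALT, allow_missing)
    )
    cap = _control_maf_mask(index, db, maf_max)
    if cap is not None:
        mask &= cap
    return _result(
        index,
        mask,
        "recessive_denovo",
        {"maf_max": maf_max, "allow_missing": allow_missing},
    )


def filter_dominant_denovo(
    index: GenotypeIndex,
    db: SampleDB,
    allow_missing: bool = False,
) -> FilterResult:
    """Novel heterozygous mutations: parents HOM_REF, affected HET.

    Parent genotypes are never rescued — an UNKNOWN parent call cannot
    prove absence.
    """
    parents, cases, _ = _groups(db)
    _require_trio_groups(parents, cases, "dominant_denovo")
    mask = _all_in_states(index, parents, frozenset({GenotypeCode.HOM_REF}))
    mask &= _all_in_states(
        index, cases, _case_states(GenotypeCode.HET, allow_missing)
    )
    return _result(
        index, mask, "dominant_denovo", {"allow_missing": allow_missing}
    )


# ---------------------------------------------------------------------------
# case-control module


def filter_case_specific(
    index: GenotypeIndex,
    db: SampleDB,
    states: Iterable[object],
    allow_missing_controls: bool = False,
) -> FilterResult:
    """Variants present in every case and absent from every control.

    ``states`` picks the required case genotype (HOM_ALT, HET, or
    HET+HOM_ALT for any non-reference call); controls must be HOM_REF,
    with UNKNOWN also tolerated under ``allow_missing_controls``.
    """
    states = normalize_states(states)
    if GenotypeCode.UNKNOWN in states:
        raise ModelError(
            "case_specific: UNKNOWN is not a selectable case state; "
            "use cases_shared to tolerate missing case genotypes"
        )
    _, cases, controls = _groups(db)
    if not cases:
        raise ModelError("case_specific: no Phenotype=2 case samples")
    mask = _all_in_states(index, cases, states)
    if controls:
        control_states = {GenotypeCode.HOM_REF}
        if allow_missing_controls:
            control_states.add(GenotypeCode.UNKNOWN)
        mask &= _all_in_states(index, controls, frozenset(control_states))
    else:
        logger.warning(
            "case_specific: no Phenotype=1 controls; the absence condition "
            "is vacuous"
        )
    return _result(
        index,
        mask,
        "case_specific",
        {
            "states": sorted(s.name for s in states),
            "allow_missing_controls": allow_missing_controls,
        },
    )


def filter_cases_shared(
    index: GenotypeIndex,
    db: SampleDB,
    states: Iterable[object],
    maf_max: float | None = None,
) -> FilterResult:
    """Variants shared by all cases; controls constrained only through the
    optional MAF cutoff.  ``states`` may include UNKNOWN to rescue
    half-genotyped cases."""
    states = normalize_states(states)
    _, cases, _ = _groups(db)
    if not cases:
        raise ModelError("cases_shared: no Phenotype=2 case samples")
    mask = _all_in_states(index, cases, states)
    cap = _control_maf_mask(index, db, maf_max)
    if cap is not None:
        mask &= cap
    return _result(
        index,
        mask,
        "cases_shared",
        {"states": sorted(s.name for s in states), "maf_max": maf_max},
    )


# ---------------------------------------------------------------------------
# population module


def _population_samples(
    db: SampleDB, population: str, sex: int | None
) -> list[str]:
    if population not in db.populations():
        raise ModelError(
            f"population {population!r} not present in the sample database "
            f"(known: {', '.join(db.populations()) or 'none'})"
        )
    samples = db.select(population=population, sex=sex)
    if not samples:
        raise ModelError(
            f"population {population!r} has no samples"
            + (f" with sex={sex}" if sex is not None else "")
        )
    return samples


def filter_pop_allele_freq(
    index: GenotypeIndex,
    db: SampleDB,
    pop_a: str,
    pop_b: str,
    maf_min_a: float,
    maf_max_b: float,
    sex: int | None = None,
) -> FilterResult:
    """Variants at MAF >= maf_min_a in population A and <= maf_max_b in B."""
    samples_a = _population_samples(db, pop_a, sex)
    samples_b = _population_samples(db, pop_b, sex)
    maf_a, _ = maf(index, samples_a)
    maf_b, _ = maf(index, samples_b)
    mask_orig = (maf_a >= maf_min_a) & (maf_b <= maf_max_b)
    return _result(
        index,
        mask_orig[index.order_map],
        "pop_allele_freq",
        {
            "pop_a": pop_a,
            "pop_b": pop_b,
            "maf_min_a": maf_min_a,
            "maf_max_b": maf_max_b,
            "sex": sex,
        },
    )


def filter_pop_individual_count(
    index: GenotypeIndex,
    db: SampleDB,
    pop_a: str,
    pop_b: str,
    state: object,
    pct_min_a: float,
    pct_max_b: float,
    sex: int | None = None,
) -> FilterResult:
    """Variants carried (in the chosen genotype state) by at least
    pct_min_a percent of population A and at most pct_max_b percent of B."""
    states = normalize_states([state])
    if states - {GenotypeCode.HET, GenotypeCode.HOM_ALT}:
        raise ModelError(
            "pop_individual_count: state must be HET or HOM_ALT"
        )
    samples_a = _population_samples(db, pop_a, sex)
    samples_b = _population_samples(db, pop_b, sex)
    frac_a = pct(index, samples_a, states)
    frac_b = pct(index, samples_b, states)
    mask_orig = (frac_a >= pct_min_a / 100.0) & (frac_b <= pct_max_b / 100.0)
    return _result(
        index,
        mask_orig[index.order_map],
        "pop_individual_count",
        {
            "pop_a": pop_a,
            "pop_b": pop_b,
            "state": sorted(s.name for s in states),
            "pct_min_a": pct_min_a,
            "pct_max_b": pct_max_b,
            "sex": sex,
        },
    )


def filter_by_sample(
    index: GenotypeIndex,
    db: SampleDB,
    samples: Sequence[str],
    states: Iterable[object],
    count_min: int = 1,
) -> FilterResult:
    """Variants where at least ``count_min`` of the named samples carry one
    of the chosen genotype states."""
    if not samples:
        raise ModelError("by_sample: no samples given")
    selected = db.select(names=samples)
    if not selected:
        raise ModelError(
            "by_sample: all requested samples are excluded (Phenotype=0)"
        )
    states = normalize_states(states)
    counts = count(index, selected, states)
    mask_orig = counts >= count_min
    return _result(
        index,
        mask_orig[index.order_map],
        "by_sample",
        {
            "samples": list(selected),
            "states": sorted(s.name for s in states),
            "count_min": count_min,
        },
    )


def count_variants(
    index: GenotypeIndex,
    db: SampleDB,
    sample: str,
    states: Iterable[object],
) -> int:
    """Number of variants where one sample's code is in ``states``.

    Works on the compressed bitmaps alone (popcount of the state bitmap);
    no variant records are materialised.
    """
    entry = db[sample]
    if entry.phenotype == 0:
        raise ModelError(f"sample {sample!r} is excluded (Phenotype=0)")
    states = normalize_states(states)
    return index.state_bitmap(sample, states).popcount()
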
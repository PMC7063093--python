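"""Deterministic synthetic VCF + PED cohorts with planted patterns.

The generator emulates the study designs the filter models serve: a
sequenced trio (two Phenotype=3 parents, one Phenotype=2 affected
offspring) plus a cohort of unrelated Phenotype=1 controls used to filter
out common variants, or several labelled populations for
frequency-contrast queries.  Selected variants are *planted* so they
satisfy a chosen model's predicate exactly; everything else is background
drawn from Hardy-Weinberg proportions at a configurable allele frequency,
with genotypes knocked out to UNKNOWN at a configurable missing rate.

Sites are independent (no linkage disequilibrium) and positions are
consecutive on one synthetic contig — sufficient for predicate testing,
not for haplotype-aware methods.  All randomness flows from the single
seed, so one spec yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .vcf_io import (
    GenotypeCode,
    GenotypeMatrix,
    VariantRecord,
    minimal_header,
    write_vcf,
)

_CONTIG = "1"
_BASES = ("A", "C", "G", "T")

TRIO_NAMES = ("father", "mother", "child")

#: trio genotype layout (father, mother, child) planted per model
_PLANT_TRIO = {
    "recessive": (GenotypeCode.HET, GenotypeCode.HET, GenotypeCode.HOM_ALT),
    "dominant": (GenotypeCode.HET, GenotypeCode.HET, GenotypeCode.HET),
    "recessive_denovo": (
        GenotypeCode.HOM_REF,
        GenotypeCode.HOM_REF,
        GenotypeCode.HOM_ALT,
    ),
    "dominant_denovo": (
        GenotypeCode.HOM_REF,
        GenotypeCode.HOM_REF,
        GenotypeCode.HET,
    ),
    "case_specific": (
        GenotypeCode.HOM_REF,
        GenotypeCode.HOM_REF,
        GenotypeCode.HOM_ALT,
    ),
    "cases_shared": (GenotypeCode.HOM_REF, GenotypeCode.HOM_REF, GenotypeCode.HET),
}
# compound het alternates the carrier parent between consecutive plants
_PLANT_COMPOUND = (
    (GenotypeCode.HET, GenotypeCode.HOM_REF, GenotypeCode.HET),
    (GenotypeCode.HOM_REF, GenotypeCode.HET, GenotypeCode.HET),
)

PLANTABLE_MODELS = tuple(_PLANT_TRIO) + ("compound_het",)


class CohortSpecError(ValueError):
    """Infeasible or inconsistent cohort specification."""


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``background_alt_rate`` is the background alternate-allele frequency
    (genotypes follow Hardy-Weinberg proportions at that frequency);
    ``missing_rate`` is the per-cell probability of an UNKNOWN call.
    ``planted`` lists (model, count, params) with params understood per
    model — ``control_carrier_freq`` makes each control independently HET
    at the planted site with that probability, and ``label`` overrides the
    truth-table label (useful to tell rare and deliberately-common plants
    of the same model apart).  When ``populations`` maps
    population names to sizes, the cohort is population-structured instead
    of trio + controls, and plants use model name ``pop_specific`` with
    params ``population`` (target), ``pct_min`` (default 10) and
    ``pct_max_others`` (default 1).
    """

    n_controls: int = 50
    n_variants: int = 1000
    seed: int = 1
    background_alt_rate: float = 0.05
    missing_rate: float = 0.02
    planted: list[tuple[str, int, dict]] = dc_field(default_factory=list)
    populations: dict[str, int] | None = None

    def validate(self) -> None:
        for name, value in (
            ("background_alt_rate", self.background_alt_rate),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise CohortSpecError(f"{name} must be in [0, 1], got {value}")
        total = sum(c for _, c, _ in self.planted)
        if total > self.n_variants:
            raise CohortSpecError(
                f"{total} planted variants exceed n_variants={self.n_variants}"
            )
        for model, count, params in self.planted:
            if count < 0:
                raise CohortSpecError(f"negative planted count for {model}")
            if self.populations is None:
                if model not in PLANTABLE_MODELS:
                    raise CohortSpecError(f"cannot plant model {model!r}")
                if model == "compound_het" and count == 1:
                    raise CohortSpecError(
                        "compound_het needs at least two planted variants"
                    )
            else:
                if model != "pop_specific":
                    raise CohortSpecError(
                        "population cohorts plant model 'pop_specific' only"
                    )
                if params.get("population") not in self.populations:
                    raise CohortSpecError(
                        f"planted population {params.get('population')!r} "
                        "not among the cohort populations"
                    )


@dataclass
class TruthTable:
    """Variant key (chrom, pos, ref, alt) -> planted model or 'background'."""

    labels: dict[tuple[str, int, str, str], str]

    def planted(self, model: str) -> set[tuple[str, int, str, str]]:
        return {k for k, v in self.labels.items() if v == model}

    def background(self) -> set[tuple[str, int, str, str]]:
        return self.planted("background")

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("chrom\tpos\tref\talt\tlabel\n")
            for (chrom, pos, ref, alt), label in sorted(
                self.labels.items(), key=lambda kv: kv[0][1]
            ):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{label}\n")


@dataclass
class Cohort:
    """In-memory generated cohort: ready to index or to write to disk."""

    header: list[str]
    records: list[VariantRecord]
    matrix: GenotypeMatrix
    ped_text: str
    truth: TruthTable


def _records(rng: np.random.Generator, n_variants: int) -> list[VariantRecord]:
    refs = rng.integers(0, 4, size=n_variants)
    alt_off = rng.integers(1, 4, size=n_variants)
    return [
        VariantRecord(
            chrom=_CONTIG,
            pos=i + 1,
            id=".",
            ref=_BASES[refs[i]],
            alt=_BASES[(refs[i] + alt_off[i]) % 4],
            qual=".",
            filter=".",
            info=".",
            original_index=i,
        )
        for i in range(n_variants)
    ]


def _background(
    rng: np.random.Generator, shape: tuple[int, int], p: float, missing: float
) -> np.ndarray:
    """Hardy-Weinberg genotypes at allele frequency p, with missingness."""
    u = rng.random(shape)
    codes = np.full(shape, int(GenotypeCode.HOM_ALT), dtype=np.uint8)
    codes[u < (1 - p) ** 2 + 2 * p * (1 - p)] = int(GenotypeCode.HET)
    codes[u < (1 - p) ** 2] = int(GenotypeCode.HOM_REF)
    if missing > 0:
        codes[rng.random(shape) < missing] = int(GenotypeCode.UNKNOWN)
    return codes


def _plant_rows(
    rng: np.random.Generator, n_variants: int, planted: list[tuple[str, int, dict]]
) -> list[tuple[int, str, dict]]:
    total = sum(c for _, c, _ in planted)
    rows = sorted(rng.choice(n_variants, size=total, replace=False).tolist())
    out: list[tuple[int, str, dict]] = []
    at = 0
    for model, count, params in planted:
        for _ in range(count):
            out.append((rows[at], model, params))
            at += 1
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Trio + controls cohort (or population cohort when
    ``spec.populations`` is set)."""
    spec.validate()
    if spec.populations is not None:
        return generate_populations(spec)
    rng = np.random.default_rng(spec.seed)

    controls = [f"ctrl{i + 1:03d}" for i in range(spec.n_controls)]
    samples = list(TRIO_NAMES) + controls
    n_s = len(samples)

    records = _records(rng, spec.n_variants)
    codes = _background(
        rng,
        (spec.n_variants, n_s),
        spec.background_alt_rate,
        spec.missing_rate,
    )

    truth = {rec.key: "background" for rec in records}
    compound_toggle = 0
    for row, model, params in _plant_rows(rng, spec.n_variants, spec.planted):
        if model == "compound_het":
            trio = _PLANT_COMPOUND[compound_toggle % 2]
            compound_toggle += 1
        else:
            trio = _PLANT_TRIO[model]
        codes[row, :3] = [int(g) for g in trio]
        carrier_freq = float(params.get("control_carrier_freq", 0.0))
        if carrier_freq > 0:
            carriers = rng.random(spec.n_controls) < carrier_freq
            codes[row, 3:] = np.where(
                carriers, int(GenotypeCode.HET), int(GenotypeCode.HOM_REF)
            )
        else:
            codes[row, 3:] = int(GenotypeCode.HOM_REF)
        truth[records[row].key] = params.get("label", model)

    ped_lines = ["IndividualID\tPhenotype\tSex\tPopulation"]
    for name, phen, sex in zip(TRIO_NAMES, (3, 3, 2), (1, 2, 1)):
        ped_lines.append(f"{name}\t{phen}\t{sex}\tNA")
    for i, name in enumerate(controls):
        ped_lines.append(f"{name}\t1\t{1 + i % 2}\tNA")

    return Cohort(
        header=minimal_header(samples, contig=_CONTIG),
        records=records,
        matrix=GenotypeMatrix(samples, codes),
        ped_text="\n".join(ped_lines) + "\n",
        truth=TruthTable(truth),
    )


def generate_populations(spec: CohortSpec) -> Cohort:
    """Population-structured cohort with planted population-specific sites.

    Background allele frequencies are drawn per variant *and* per
    population, uniform on [0, 2 * background_alt_rate] (so the requested
    rate is the mean), which gives every population its own frequency
    profile.  A planted population-specific site has exactly
    ``ceil(pct_min% of the target population)`` HET carriers there and no
    carriers elsewhere, satisfying a pct_min / pct_max_others
    individual-count query by construction.
    """
    spec.validate()
    if not spec.populations:
        raise CohortSpecError("populations map must be nonempty")
    rng = np.random.default_rng(spec.seed)

    pops = list(spec.populations.items())
    samples: list[str] = []
    pop_slices: dict[str, slice] = {}
    at = 0
    for pop, size in pops:
        if size < 1:
            raise CohortSpecError(f"population {pop!r} has size {size}")
        samples.extend(f"{pop}_{i + 1:03d}" for i in range(size))
        pop_slices[pop] = slice(at, at + size)
        at += size
    n_s = len(samples)

    records = _records(rng, spec.n_variants)
    codes = np.empty((spec.n_variants, n_s), dtype=np.uint8)
    for pop, size in pops:
        freqs = rng.uniform(0, 2 * spec.background_alt_rate, size=spec.n_variants)
        u = rng.random((spec.n_variants, size))
        block = np.full((spec.n_variants, size), int(GenotypeCode.HOM_ALT), np.uint8)
        p = freqs[:, None]
        block[u < (1 - p) ** 2 + 2 * p * (1 - p)] = int(GenotypeCode.HET)
        block[u < (1 - p) ** 2] = int(GenotypeCode.HOM_REF)
        codes[:, pop_slices[pop]] = block
    if spec.missing_rate > 0:
        codes[rng.random(codes.shape) < spec.missing_rate] = int(
            GenotypeCode.UNKNOWN
        )

    truth = {rec.key: "background" for rec in records}
    for row, model, params in _plant_rows(rng, spec.n_variants, spec.planted):
        target = params["population"]
        pct_min = float(params.get("pct_min", 10.0))
        size = spec.populations[target]
        n_carriers = max(1, math.ceil(pct_min / 100.0 * size))
        codes[row, :] = int(GenotypeCode.HOM_REF)
        sl = pop_slices[target]
        carriers = rng.choice(size, size=n_carriers, replace=False)
        codes[row, sl.start + carriers] = int(GenotypeCode.HET)
        truth[records[row].key] = params.get("label", model)

    ped_lines = ["IndividualID\tPhenotype\tSex\tPopulation"]
    i = 0
    for pop, size in pops:
        for j in range(size):
            ped_lines.append(f"{pop}_{j + 1:03d}\t1\t{1 + i % 2}\t{pop}")
            i += 1

    return Cohort(
        header=minimal_header(samples, contig=_CONTIG),
        records=records,
        matrix=GenotypeMatrix(samples, codes),
        ped_text="\n".join(ped_lines) + "\n",
        truth=TruthTable(truth),
    )


def write_cohort(
    spec: CohortSpec, out_dir: str | Path, prefix: str = "cohort"
) -> tuple[Path, Path, Path, TruthTable]:
    """Generate and write <prefix>.vcf, <prefix>.ped and <prefix>.truth.tsv.

    Identical specs (same seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    vcf_path = out_dir / f"{prefix}.vcf"
    ped_path = out_dir / f"{prefix}.ped"
    truth_path = out_dir / f"{prefix}.truth.tsv"
    write_vcf(cohort.header, cohort.records, cohort.matrix, vcf_path)
    with open(ped_path, "w", encoding="utf-8") as fh:
        fh.write(cohort.ped_text)
    cohort.truth.write(truth_path)
    return vcf_path, ped_path, truth_path, cohort.truth
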
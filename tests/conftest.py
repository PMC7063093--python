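"""Shared fixtures: a toy hand-checked VCF and randomized cohorts.

``make_random_cohort`` builds a trio + mixed controls/populations cohort
directly as a genotype matrix (independent of the synthetic-cohort
generator) so engine-vs-oracle comparisons exercise arbitrary genotype
configurations, not just generator output.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from genoquery import GenotypeMatrix, VariantRecord, build_index
from genoquery.sample_db import PedRow, PedTable, create_sample_db

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tA\tC\t50\tPASS\tDP=10\tGT\t0/0\t0/1
1\t200\trs1\tG\tT\t.\t.\t.\tGT\t1/1\t./.
1\t300\t.\tT\tA,G\t12.5\tq10\tAC=3\tGT\t0|1\t1/2
"""

# expected codes for TOY_VCF (rows x samples)
TOY_CODES = [[0, 1], [2, 3], [1, 2]]


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def make_records(n_variants: int) -> list[VariantRecord]:
    return [
        VariantRecord("1", i + 1, ".", "A", "C", ".", ".", ".", i)
        for i in range(n_variants)
    ]


def make_random_cohort(
    seed: int,
    n_samples: int | None = None,
    n_variants: int | None = None,
):
    """Trio (cols 0-2, phenotypes 3,3,2) + controls split over two
    populations, with random genotypes, phenotype-0 samples, and missing
    calls.  Returns matrix, index, sample db, and the column groups the
    oracle needs."""
    rng = np.random.default_rng(seed)
    n_s = int(n_samples or rng.integers(12, 101))
    n_v = int(n_variants or rng.integers(100, 2001))
    alt_rate = float(rng.uniform(0.01, 0.30))
    missing_rate = float(rng.uniform(0.0, 0.10))

    p = alt_rate  # Hardy-Weinberg at allele frequency p
    u = rng.random((n_v, n_s))
    codes = np.full((n_v, n_s), 2, dtype=np.uint8)
    codes[u < (1 - p) ** 2 + 2 * p * (1 - p)] = 1
    codes[u < (1 - p) ** 2] = 0
    codes[rng.random((n_v, n_s)) < missing_rate] = 3

    names = [f"s{i:03d}" for i in range(n_s)]
    # trio + four guaranteed controls covering both populations and sexes,
    # then random phenotype 0/1 for the rest
    phen = [3, 3, 2, 1, 1, 1, 1]
    pops = [None, None, None, "POPA", "POPA", "POPB", "POPB"]
    sexes = [1, 2, 1, 1, 2, 1, 2]
    for _ in range(n_s - 7):
        phen.append(int(rng.choice([0, 1], p=[0.1, 0.9])))
        pops.append(str(rng.choice(["POPA", "POPB"])))
        sexes.append(int(rng.choice([1, 2])))

    rows = [
        PedRow(names[i], phen[i], sexes[i], pops[i]) for i in range(n_s)
    ]
    ped = PedTable(rows, has_phenotype=True, has_sex=True, has_population=True)
    records = make_records(n_v)
    matrix = GenotypeMatrix(names, codes)
    index = build_index(records, matrix)
    db = create_sample_db(ped, index)

    def cols(pred):
        return [i for i in range(n_s) if phen[i] != 0 and pred(i)]

    return SimpleNamespace(
        rng=rng,
        records=records,
        matrix=matrix,
        index=index,
        db=db,
        names=names,
        parents=cols(lambda i: phen[i] == 3),
        cases=cols(lambda i: phen[i] == 2),
        controls=cols(lambda i: phen[i] == 1),
        pop_cols={
            pop: cols(lambda i: pops[i] == pop) for pop in ("POPA", "POPB")
        },
        pop_sex_cols={
            (pop, sex): cols(lambda i: pops[i] == pop and sexes[i] == sex)
            for pop in ("POPA", "POPB")
            for sex in (1, 2)
        },
        alt_rate=alt_rate,
        missing_rate=missing_rate,
    )


@pytest.fixture
def small_cohort():
    return make_random_cohort(seed=7, n_samples=20, n_variants=200)
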
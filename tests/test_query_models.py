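"""Filter-model semantics: pinned trio examples, primitives against scan
oracles, engine/oracle equivalence on randomized cohorts, monotonicity."""

import numpy as np
import pytest

import _oracle as oracle
from genoquery import (
    GenotypeCode,
    GenotypeMatrix,
    build_index,
    count,
    count_variants,
    create_sample_db,
    filter_by_sample,
    filter_case_specific,
    filter_cases_shared,
    filter_compound_het,
    filter_dominant,
    filter_dominant_denovo,
    filter_pop_allele_freq,
    filter_pop_individual_count,
    filter_recessive,
    filter_recessive_denovo,
    maf,
    pct,
)
from genoquery.query_models import ModelError, normalize_states
from genoquery.sample_db import PedRow, PedTable

from conftest import make_random_cohort, make_records

R, H, A, U = 0, 1, 2, 3  # HOM_REF, HET, HOM_ALT, UNKNOWN


def trio_setup(rows, controls=2, parents=2):
    """Cohort of [parents..., kid, controls...] from explicit code rows."""
    codes = np.asarray(rows, dtype=np.uint8)
    n = codes.shape[1]
    parent_names = [f"p{i}" for i in range(parents)]
    names = parent_names + ["kid"] + [f"c{i}" for i in range(n - parents - 1)]
    assert len(names) == n
    ped_rows = (
        [PedRow(p, 3, 1, None) for p in parent_names]
        + [PedRow("kid", 2, 1, None)]
        + [PedRow(c, 1, 2, None) for c in names[parents + 1 :]]
    )
    ped = PedTable(ped_rows, True, True, False)
    matrix = GenotypeMatrix(names, codes)
    index = build_index(make_records(codes.shape[0]), matrix)
    return index, create_sample_db(ped, index)


def kept(result):
    return result.original_indices


class TestPrimitives:
    def test_count_all_states_is_constant(self, small_cohort):
        samples = small_cohort.db.select(phenotype={1})
        vec = count(small_cohort.index, samples, set(GenotypeCode))
        assert (vec == len(samples)).all()

    def test_count_trio_example(self):
        index, db = trio_setup([[H, H, A, R, R]])
        assert count(index, db.select(phenotype={3}), {"het"}).tolist() == [2]

    def test_count_pct_match_scan_oracle(self):
        cohort = make_random_cohort(3, n_samples=20, n_variants=50)
        rng = np.random.default_rng(0)
        for _ in range(10):
            cols = sorted(
                rng.choice(len(cohort.names), size=int(rng.integers(1, 8)), replace=False)
            )
            samples = [cohort.names[c] for c in cols]
            states = set(
                rng.choice([0, 1, 2, 3], size=int(rng.integers(1, 4)), replace=False)
            )
            got = count(cohort.index, samples, {int(s) for s in states})
            want = [
                oracle.row_count(cohort.matrix.codes[v], cols, states)
                for v in range(50)
            ]
            assert got.tolist() == want
            np.testing.assert_array_equal(
                pct(cohort.index, samples, {int(s) for s in states}),
                np.array(want) / len(samples),
            )

    def test_maf_direct_allele_count(self):
        index, db = trio_setup([[H, A, R, R, R]], parents=2)
        # codes over all five samples: HET, HOM_ALT, HOM_REF, HOM_REF, HOM_REF
        vals, uncalled = maf(index, db.select())
        # called alleles 10, alt alleles 3 over the full roster? restrict to
        # the worked set [HET, HOM_ALT, HOM_REF, HOM_REF]:
        vals4, _ = maf(index, db.select()[:4])
        assert vals4.tolist() == [3 / 8]
        assert not uncalled.any()

    def test_maf_all_hom_ref_and_all_unknown(self):
        index, db = trio_setup([[R, R, R, R, R], [U, U, U, U, U]])
        vals, uncalled = maf(index, db.select())
        assert vals.tolist() == [0.0, 0.0]
        assert uncalled.tolist() == [False, True]

    def test_boundary_single_sample_pct(self):
        index, db = trio_setup([[H, R, R, R, R], [R, R, R, R, R]])
        assert pct(index, ["p0"], {"het"}).tolist() == [1.0, 0.0]

    def test_states_normalization(self):
        assert normalize_states(["het_hom_alt"]) == {
            GenotypeCode.HET,
            GenotypeCode.HOM_ALT,
        }
        with pytest.raises(ModelError, match="unknown genotype state"):
            normalize_states(["weird"])
        with pytest.raises(ModelError, match="nonempty"):
            normalize_states([])


class TestRecessive:
    def test_carrier_parents_hom_alt_child_kept(self):
        index, db = trio_setup([[H, H, A, R, R]])
        assert kept(filter_recessive(index, db, maf_max=0.1)) == [0]

    def test_hom_alt_parent_dropped(self):
        index, db = trio_setup([[A, H, A, R, R]])
        assert kept(filter_recessive(index, db)) == []

    def test_unknown_child_rescued_only_when_allowed(self):
        index, db = trio_setup([[H, H, U, R, R]])
        assert kept(filter_recessive(index, db, allow_missing=True)) == [0]
        assert kept(filter_recessive(index, db, allow_missing=False)) == []

    def test_unknown_parent_never_rescued(self):
        index, db = trio_setup([[U, H, A, R, R]])
        assert kept(filter_recessive(index, db, allow_missing=True)) == []

    def test_control_maf_cap(self):
        # controls HET,HET -> MAF 0.5; cap 0.1 drops, cap 0.5 keeps
        index, db = trio_setup([[H, H, A, H, H]])
        assert kept(filter_recessive(index, db, maf_max=0.1)) == []
        assert kept(filter_recessive(index, db, maf_max=0.5)) == [0]

    def test_missing_groups_raise(self):
        index, db = trio_setup([[R, R, R]], parents=0, controls=2)
        with pytest.raises(ModelError, match="case-specific|case-control"):
            filter_recessive(index, db)


class TestCompoundHet:
    def test_two_complementary_candidates_kept(self):
        index, db = trio_setup(
            [[H, R, H, R, R], [R, H, H, R, R], [H, H, H, R, R]]
        )
        assert kept(filter_compound_het(index, db)) == [0, 1]

    def test_single_candidate_yields_empty_with_note(self):
        index, db = trio_setup([[H, R, H, R, R], [R, R, R, R, R]])
        result = filter_compound_het(index, db)
        assert result.n_total == 0
        assert "two" in result.note

    def test_both_parents_het_dropped(self):
        index, db = trio_setup([[H, H, H, R, R], [H, R, H, R, R], [R, H, H, R, R]])
        assert 0 not in kept(filter_compound_het(index, db))

    def test_requires_exactly_two_parents(self):
        index, db = trio_setup([[H, H, R, R]], parents=1)
        with pytest.raises(ModelError, match="exactly 2"):
            filter_compound_het(index, db)


class TestDominantFamily:
    def test_dominant_het_parent_and_child(self):
        index, db = trio_setup([[H, H, R, R], [H, R, R, R]], parents=1)
        assert kept(filter_dominant(index, db)) == [0]

    def test_dominant_hom_alt_parent_dropped(self):
        index, db = trio_setup([[A, H, R, R]], parents=1)
        assert kept(filter_dominant(index, db)) == []

    def test_dominant_without_parents_suggests_case_specific(self):
        index, db = trio_setup([[H, R, R]], parents=0)
        with pytest.raises(ModelError, match="case-specific"):
            filter_dominant(index, db)

    def test_recessive_denovo(self):
        index, db = trio_setup([[R, R, A, R, R], [H, R, A, R, R]])
        assert kept(filter_recessive_denovo(index, db)) == [0]

    def test_recessive_denovo_control_maf_cap(self):
        # 5 controls, one HET -> MAF 0.1; cap 0.05 drops it
        index, db = trio_setup([[R, R, A, H, R, R, R, R]])
        assert kept(filter_recessive_denovo(index, db, maf_max=0.05)) == []
        assert kept(filter_recessive_denovo(index, db, maf_max=0.1)) == [0]

    def test_dominant_denovo(self):
        index, db = trio_setup(
            [[R, R, H, R, R], [R, R, A, R, R], [U, R, H, R, R]]
        )
        assert kept(filter_dominant_denovo(index, db)) == [0]
        # parent UNKNOWN is never rescued
        assert kept(filter_dominant_denovo(index, db, allow_missing=True)) == [0]


class TestCaseControl:
    def two_case_setup(self, rows):
        codes = np.asarray(rows, dtype=np.uint8)
        names = ["case1", "case2", "c0", "c1", "c2"]
        ped = PedTable(
            [PedRow(n, 2 if n.startswith("case") else 1, 1, None) for n in names],
            True,
            True,
            False,
        )
        matrix = GenotypeMatrix(names, codes)
        index = build_index(make_records(codes.shape[0]), matrix)
        return index, create_sample_db(ped, index)

    def test_case_specific_hom_alt(self):
        index, db = self.two_case_setup([[A, A, R, R, R], [A, A, R, H, R]])
        assert kept(filter_case_specific(index, db, {"hom_alt"})) == [0]

    def test_case_specific_het_hom_alt_mixture(self):
        index, db = self.two_case_setup([[H, A, R, R, R]])
        assert kept(filter_case_specific(index, db, {"het_hom_alt"})) == [0]
        assert kept(filter_case_specific(index, db, {"hom_alt"})) == []

    def test_case_specific_missing_control_flag(self):
        index, db = self.two_case_setup([[A, A, U, R, R]])
        assert kept(filter_case_specific(index, db, {"hom_alt"})) == []
        assert kept(
            filter_case_specific(index, db, {"hom_alt"}, allow_missing_controls=True)
        ) == [0]

    def test_case_specific_rejects_unknown_state(self):
        index, db = self.two_case_setup([[A, A, R, R, R]])
        with pytest.raises(ModelError, match="UNKNOWN"):
            filter_case_specific(index, db, {"unknown"})

    def test_cases_shared_ignores_controls_without_cap(self):
        index, db = self.two_case_setup([[H, H, H, R, R]])
        assert kept(filter_cases_shared(index, db, {"het"})) == [0]

    def test_cases_shared_maf_cap(self):
        # control cohort genotypes HET,R,R,R? MAF with 3 controls: HET -> 1/6
        index, db = self.two_case_setup([[H, H, H, R, R]])
        assert kept(filter_cases_shared(index, db, {"het"}, maf_max=0.05)) == []
        assert kept(filter_cases_shared(index, db, {"het"}, maf_max=1 / 6)) == [0]

    def test_cases_shared_unknown_state_rescues(self):
        index, db = self.two_case_setup([[H, U, R, R, R]])
        assert kept(filter_cases_shared(index, db, {"het"})) == []
        assert kept(filter_cases_shared(index, db, {"het", "unknown"})) == [0]


class TestPopulation:
    def pop_setup(self, codes_a, codes_b, sexes=None):
        codes = np.asarray(
            [list(ra) + list(rb) for ra, rb in zip(codes_a, codes_b)], np.uint8
        )
        na, nb = len(codes_a[0]), len(codes_b[0])
        names = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        pops = ["FIN"] * na + ["GBR"] * nb
        sexes = sexes or [1] * (na + nb)
        ped = PedTable(
            [PedRow(n, 1, s, p) for n, s, p in zip(names, sexes, pops)],
            True,
            True,
            True,
        )
        matrix = GenotypeMatrix(names, codes)
        index = build_index(make_records(codes.shape[0]), matrix)
        return index, create_sample_db(ped, index)

    def test_allele_freq_thresholds(self):
        # FIN: HET,HET,HOM_ALT,HOM_REF -> MAF 0.5; GBR: R,R,R,HET -> 0.125
        index, db = self.pop_setup(
            [[H, H, A, R]], [[R, R, R, H]]
        )
        kept_fwd = kept(
            filter_pop_allele_freq(index, db, "FIN", "GBR", 0.3, 0.2)
        )
        assert kept_fwd == [0]
        # swapped thresholds: needs FIN<=0.2 impossible
        assert (
            kept(filter_pop_allele_freq(index, db, "GBR", "FIN", 0.3, 0.2)) == []
        )

    def test_unknown_population_raises(self):
        index, db = self.pop_setup([[R]], [[R]])
        with pytest.raises(ModelError, match="IBS"):
            filter_pop_allele_freq(index, db, "IBS", "GBR", 0.1, 0.1)

    def test_individual_count_inclusive_boundaries(self):
        # 10 FIN (1 HET = 10%), 4 GBR (0 carriers)
        fin = [[H] + [R] * 9]
        gbr = [[R] * 4]
        index, db = self.pop_setup(fin, gbr)
        assert kept(
            filter_pop_individual_count(index, db, "FIN", "GBR", "het", 10.0, 1.0)
        ) == [0]
        assert (
            kept(
                filter_pop_individual_count(
                    index, db, "FIN", "GBR", "het", 10.1, 1.0
                )
            )
            == []
        )

    def test_sex_restriction(self):
        # one variant, carriers only among males of FIN
        index, db = self.pop_setup(
            [[H, R]], [[R, R]], sexes=[1, 2, 1, 2]
        )
        males = kept(
            filter_pop_allele_freq(index, db, "FIN", "GBR", 0.25, 0.0, sex=1)
        )
        females = kept(
            filter_pop_allele_freq(index, db, "FIN", "GBR", 0.25, 0.0, sex=2)
        )
        assert males == [0] and females == []

    def test_by_sample_count_threshold(self):
        index, db = self.pop_setup([[H, H, R]], [[R]])
        samples = ["a0", "a1", "a2"]
        assert kept(filter_by_sample(index, db, samples, {"het"}, 2)) == [0]
        assert kept(filter_by_sample(index, db, samples, {"het"}, 3)) == []

    def test_variant_count(self):
        index, db = self.pop_setup(
            [[H], [R], [H], [A], [R]], [[R], [R], [R], [R], [R]]
        )
        assert count_variants(index, db, "a0", {"het"}) == 2
        assert count_variants(index, db, "a0", set(GenotypeCode)) == 5


def run_engine(cohort, model, params):
    index, db = cohort.index, cohort.db
    if model == "recessive":
        return set(kept(filter_recessive(index, db, **params)))
    if model == "compound_het":
        return set(kept(filter_compound_het(index, db, **params)))
    if model == "dominant":
        return set(kept(filter_dominant(index, db, **params)))
    if model == "recessive_denovo":
        return set(kept(filter_recessive_denovo(index, db, **params)))
    if model == "dominant_denovo":
        return set(kept(filter_dominant_denovo(index, db, allow_missing=params["allow_missing"])))
    if model == "case_specific":
        return set(
            kept(
                filter_case_specific(
                    index, db, params["states"], params["allow_missing_controls"]
                )
            )
        )
    if model == "cases_shared":
        return set(
            kept(filter_cases_shared(index, db, params["states"], params["maf_max"]))
        )
    if model == "pop_allele_freq":
        return set(
            kept(
                filter_pop_allele_freq(
                    index, db, "POPA", "POPB", params["maf_min"], params["maf_max"]
                )
            )
        )
    if model == "pop_individual_count":
        return set(
            kept(
                filter_pop_individual_count(
                    index,
                    db,
                    "POPA",
                    "POPB",
                    params["state"],
                    params["pct_min"],
                    params["pct_max"],
                )
            )
        )
    if model == "by_sample":
        return set(
            kept(
                filter_by_sample(
                    index, db, params["samples"], params["states"], params["count_min"]
                )
            )
        )
    raise AssertionError(model)


def run_oracle(cohort, model, params):
    codes = cohort.matrix.codes
    p, c, k = cohort.parents, cohort.cases, cohort.controls
    if model == "recessive":
        return oracle.scan_recessive(codes, p, c, k, **params)
    if model == "compound_het":
        return oracle.scan_compound_het(codes, p, c, k, **params)
    if model == "dominant":
        return oracle.scan_dominant(codes, p, c, k, **params)
    if model == "recessive_denovo":
        return oracle.scan_recessive_denovo(codes, p, c, k, **params)
    if model == "dominant_denovo":
        return oracle.scan_dominant_denovo(codes, p, c, params["allow_missing"])
    if model == "case_specific":
        states = {int(s) for s in normalize_states(params["states"])}
        return oracle.scan_case_specific(
            codes, c, k, states, params["allow_missing_controls"]
        )
    if model == "cases_shared":
        states = {int(s) for s in normalize_states(params["states"])}
        return oracle.scan_cases_shared(codes, c, k, states, params["maf_max"])
    if model == "pop_allele_freq":
        return oracle.scan_pop_allele_freq(
            codes,
            cohort.pop_cols["POPA"],
            cohort.pop_cols["POPB"],
            params["maf_min"],
            params["maf_max"],
        )
    if model == "pop_individual_count":
        state = int(next(iter(normalize_states([params["state"]]))))
        return oracle.scan_pop_individual_count(
            codes,
            cohort.pop_cols["POPA"],
            cohort.pop_cols["POPB"],
            state,
            params["pct_min"],
            params["pct_max"],
        )
    if model == "by_sample":
        cols = [cohort.names.index(s) for s in params["samples"]]
        states = {int(s) for s in normalize_states(params["states"])}
        return oracle.scan_by_sample(codes, cols, states, params["count_min"])
    raise AssertionError(model)


def random_params(rng, model, cohort):
    maf_max = rng.choice([None, 0.0, 0.02, 0.05, 0.1, 0.3])
    maf_max = None if maf_max is None else float(maf_max)
    allow = bool(rng.choice([True, False]))
    if model in ("recessive", "compound_het", "dominant", "recessive_denovo"):
        return {"maf_max": maf_max, "allow_missing": allow}
    if model == "dominant_denovo":
        return {"allow_missing": allow}
    if model == "case_specific":
        states = [str(rng.choice(["hom_alt", "het", "het_hom_alt"]))]
        return {"states": states, "allow_missing_controls": allow}
    if model == "cases_shared":
        states = [str(rng.choice(["hom_alt", "het", "het_hom_alt", "unknown"]))]
        if bool(rng.choice([True, False])):
            states.append("unknown")
        return {"states": states, "maf_max": maf_max}
    if model == "pop_allele_freq":
        return {
            "maf_min": float(rng.choice([0.0, 0.05, 0.1, 0.3])),
            "maf_max": float(rng.choice([0.0, 0.05, 0.2, 1.0])),
        }
    if model == "pop_individual_count":
        return {
            "state": str(rng.choice(["het", "hom_alt"])),
            "pct_min": float(rng.choice([0.0, 1.0, 10.0, 25.0])),
            "pct_max": float(rng.choice([0.0, 1.0, 10.0, 100.0])),
        }
    if model == "by_sample":
        size = int(rng.integers(1, min(6, len(cohort.names))))
        cols = rng.choice(len(cohort.names), size=size, replace=False)
        samples = [
            cohort.names[i]
            for i in sorted(int(c) for c in cols)
            if cohort.db[cohort.names[i]].phenotype != 0
        ]
        if not samples:
            samples = [cohort.names[0]]
        return {
            "samples": samples,
            "states": [str(rng.choice(["het", "hom_alt", "het_hom_alt"]))],
            "count_min": int(rng.integers(1, len(samples) + 1)),
        }
    raise AssertionError(model)


SCAN_MODELS = (
    "recessive",
    "compound_het",
    "dominant",
    "recessive_denovo",
    "dominant_denovo",
    "case_specific",
    "cases_shared",
    "pop_allele_freq",
    "pop_individual_count",
    "by_sample",
)


@pytest.mark.parametrize("seed", range(8))
def test_engine_matches_scan_oracle(seed):
    """Index-backed filtering equals a naive variant-centric scan for every
    model on a randomized cohort."""
    cohort = make_random_cohort(100 + seed, n_samples=25, n_variants=300)
    rng = np.random.default_rng(seed)
    for model in SCAN_MODELS:
        params = random_params(rng, model, cohort)
        assert run_engine(cohort, model, params) == run_oracle(
            cohort, model, params
        ), model
    # variant_count primitive as well
    name = cohort.names[int(rng.integers(0, len(cohort.names)))]
    if cohort.db[name].phenotype != 0:
        assert count_variants(cohort.index, cohort.db, name, {"het"}) == (
            oracle.scan_variant_count(
                cohort.matrix.codes, cohort.names.index(name), {1}
            )
        )


def test_rescue_soundness_and_monotonicity():
    """allow_missing=False results are subsets of allow_missing=True;
    tightening maf_max only removes variants."""
    cohort = make_random_cohort(42, n_samples=30, n_variants=400)
    for model in ("recessive", "compound_het", "dominant", "recessive_denovo"):
        strict = run_engine(cohort, model, {"maf_max": None, "allow_missing": False})
        loose = run_engine(cohort, model, {"maf_max": None, "allow_missing": True})
        assert strict <= loose, model
        prev = loose
        for maf_max in (0.3, 0.1, 0.02, 0.0):
            cur = run_engine(
                cohort, model, {"maf_max": maf_max, "allow_missing": True}
            )
            assert cur <= prev, (model, maf_max)
            prev = cur


def test_count_min_monotonicity():
    cohort = make_random_cohort(43, n_samples=20, n_variants=300)
    samples = cohort.db.select(phenotype={1})[:5]
    prev = None
    for count_min in range(1, len(samples) + 1):
        cur = set(
            kept(
                filter_by_sample(
                    cohort.index, cohort.db, samples, {"het_hom_alt"}, count_min
                )
            )
        )
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_planted_pattern_recovery_and_near_miss_exclusion():
    """Variants planted to satisfy a model are returned; flipping one
    sample's genotype off the pattern removes the variant."""
    index, db = trio_setup(
        [
            [H, H, A, R, R],  # recessive plant
            [H, H, A, R, R],
            [A, H, A, R, R],  # near miss: father not HET
            [H, H, H, R, R],  # near miss: child not HOM_ALT
        ]
    )
    got = kept(filter_recessive(index, db))
    assert got == [0, 1]
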
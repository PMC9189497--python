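"""Karyotype fitness summaries, AOD, load decomposition and the outcome
classifier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aodsim
from aodsim.fixtures import FixtureSpec, IndividualSpec, make_population
from aodsim.stats import (
    KaryotypeFitnessSummary,
    OUTCOME_BALANCED_LETHAL,
    OUTCOME_HALF_LETHAL,
    OUTCOME_POLY_BOTH_VIABLE,
    bin_invasion_by_aod_symmetry,
    classify_from_means,
    classify_outcome,
    compute_aod,
    compute_loads,
    expected_karyotype_fitness,
    karyotype_fitness_summary,
    mutations_per_arrangement,
)
from aodsim.wf_engine import ARR_A, ARR_B


def summary(W_AA=1.0, W_AB=1.0, W_BB=1.0, gen=0):
    return KaryotypeFitnessSummary(W_AA, W_AB, W_BB, 1, 1, 1, gen)


def spec_pop(individuals, mutations=(), fixed=()):
    return make_population(FixtureSpec(individuals=list(individuals),
                                       mutations=list(mutations),
                                       fixed=tuple(fixed)))


class TestKaryotypeSummary:
    def test_constant_fitness(self):
        pop = spec_pop([IndividualSpec(ARR_A, (), ARR_A),
                        IndividualSpec(ARR_A, (), ARR_B),
                        IndividualSpec(ARR_B, (), ARR_B)])
        s = karyotype_fitness_summary(pop)
        assert (s.W_AA, s.W_AB, s.W_BB) == (1.0, 1.0, 1.0)
        assert (s.n_AA, s.n_AB, s.n_BB) == (1, 1, 1)

    def test_hand_means_and_absent_class(self):
        # two AA at fitness 0.4/0.6 (homozygous s=-0.6 / s=-0.4), one AB at 1.0
        muts = [(100, -0.6, 0.0), (5_100, -0.4, 0.0)]
        pop = spec_pop([IndividualSpec(ARR_A, (0,), ARR_A, (0,)),
                        IndividualSpec(ARR_A, (1,), ARR_A, (1,)),
                        IndividualSpec(ARR_A, (), ARR_B, ())], muts)
        s = karyotype_fitness_summary(pop)
        assert s.W_AA == pytest.approx(0.5)
        assert s.W_AB == 1.0
        assert math.isnan(s.W_BB) and s.n_BB == 0

    def test_order_invariance(self):
        muts = [(100, -0.5, 0.0)]
        inds = [IndividualSpec(ARR_A, (0,), ARR_A, (0,)),
                IndividualSpec(ARR_A, (), ARR_B),
                IndividualSpec(ARR_B, (), ARR_B)]
        s1 = karyotype_fitness_summary(spec_pop(inds, muts))
        s2 = karyotype_fitness_summary(spec_pop(inds[::-1], muts))
        assert (s1.W_AA, s1.W_AB, s1.W_BB) == (s2.W_AA, s2.W_AB, s2.W_BB)


class TestAOD:
    def test_no_selection(self):
        rec = compute_aod(summary(1.0, 1.0, 1.0))
        assert rec.sp == 0.0 and rec.symmetry == 0.0

    def test_hand_arithmetic(self):
        rec = compute_aod(summary(0.8, 1.0, 0.9))
        assert rec.s1p == pytest.approx(0.2)
        assert rec.s2p == pytest.approx(0.1)
        assert rec.sp == pytest.approx(0.1)
        assert rec.symmetry == pytest.approx(0.1)

    def test_negative_aod_when_homokaryotype_fitter(self):
        rec = compute_aod(summary(1.2, 1.0, 1.0))
        assert rec.sp == pytest.approx(-0.2)

    def test_undefined_when_heterokaryotype_missing_or_dead(self):
        rec = compute_aod(KaryotypeFitnessSummary(0.5, math.nan, 0.5, 1, 0, 1))
        assert math.isnan(rec.sp) and math.isnan(rec.s1p)
        rec = compute_aod(KaryotypeFitnessSummary(0.5, 0.0, 0.5, 1, 2, 1))
        assert math.isnan(rec.sp)

    def test_missing_homokaryotype_component_undefined(self):
        rec = compute_aod(KaryotypeFitnessSummary(math.nan, 1.0, 0.9, 0, 2, 1))
        assert math.isnan(rec.s1p)
        assert rec.s2p == pytest.approx(0.1)
        assert math.isnan(rec.sp)

    def test_brute_force_oracle_on_random_populations(self, rng):
        """AOD from the summary equals a direct recomputation from raw
        per-individual fitness lists."""
        for _ in range(100):
            n = int(rng.integers(6, 20))
            muts = [(100 + 5000 * i, float(-rng.uniform(0.01, 0.5)), float(rng.uniform(0, 0.3)))
                    for i in range(6)]
            inds = []
            for _ in range(n):
                arr1, arr2 = rng.integers(0, 2, size=2)
                m1 = tuple(int(i) for i in np.flatnonzero(rng.random(6) < 0.4))
                m2 = tuple(int(i) for i in np.flatnonzero(rng.random(6) < 0.4))
                inds.append(IndividualSpec(int(arr1), m1, int(arr2), m2))
            pop = spec_pop(inds, muts)
            rec = compute_aod(karyotype_fitness_summary(pop))
            by_k = {"AA": [], "AB": [], "BB": []}
            for ind in pop.individuals:
                by_k[aodsim.karyotype(ind)].append(ind.fitness)
            if not by_k["AB"] or np.mean(by_k["AB"]) == 0:
                assert math.isnan(rec.sp)
                continue
            wab = np.mean(by_k["AB"])
            if by_k["AA"] and by_k["BB"]:
                s1 = 1 - np.mean(by_k["AA"]) / wab
                s2 = 1 - np.mean(by_k["BB"]) / wab
                assert rec.s1p == pytest.approx(s1)
                assert rec.s2p == pytest.approx(s2)
                assert rec.sp == pytest.approx(min(s1, s2))
                assert rec.symmetry == pytest.approx(abs(s1 - s2))


class TestLoads:
    def test_no_mutations(self):
        pop = spec_pop([IndividualSpec(ARR_B, (), ARR_B)])
        L = compute_loads(pop, (0, 10_000_000))
        assert (L.drift_load, L.mutational_load, L.segregation_load) == (0, 0, 0)

    def test_private_fixed_drift_load(self):
        muts = [(2_500_100, -0.1, 0.0)]
        pop = spec_pop([IndividualSpec(ARR_B, (), ARR_B)], muts, fixed=(0,))
        L = compute_loads(pop, (2_500_000, 7_500_000), reference=set())
        assert L.drift_load == pytest.approx(0.1)
        assert L.mutational_load == 0.0
        assert L.segregation_load == pytest.approx(0.1)
        assert L.drift_fraction == pytest.approx(1.0)

    def test_multiplicative_composition(self):
        # one private fixed (s=-0.2) and one segregating homozygous (s=-0.1)
        muts = [(2_500_100, -0.2, 0.0), (3_000_100, -0.1, 0.0)]
        pop = spec_pop([IndividualSpec(ARR_B, (1,), ARR_B, (1,))], muts, fixed=(0,))
        L = compute_loads(pop, (2_500_000, 7_500_000))
        assert L.drift_load == pytest.approx(0.2)
        assert L.mutational_load == pytest.approx(0.1)
        assert L.segregation_load == pytest.approx(1 - 0.8 * 0.9)
        assert L.drift_fraction == pytest.approx(0.2 / (1 - 0.72))

    def test_region_restriction_and_shared_fixed_excluded(self):
        muts = [(100, -0.5, 0.0), (2_500_100, -0.1, 0.0)]
        pop = spec_pop([IndividualSpec(ARR_B, (), ARR_B)], muts, fixed=(0, 1))
        # mutation 0 outside the supergene region; reference shares nothing
        L = compute_loads(pop, (2_500_000, 7_500_000), reference=set())
        assert L.drift_load == pytest.approx(0.1)
        # reference population also fixed for mutation 1: nothing private
        L2 = compute_loads(pop, (2_500_000, 7_500_000),
                           reference={int(pop.catalog.pos.tolist().index(2_500_100))})
        assert L2.drift_load == 0.0


class TestClassifier:
    @pytest.mark.parametrize("waa,wbb,expected", [
        (0.5, 0.6, OUTCOME_POLY_BOTH_VIABLE),
        (0.005, 0.5, OUTCOME_HALF_LETHAL),
        (0.5, 0.005, OUTCOME_HALF_LETHAL),
        (0.005, 0.003, OUTCOME_BALANCED_LETHAL),
    ])
    def test_from_means(self, waa, wbb, expected):
        assert classify_from_means(waa, wbb, 0.01) == expected

    def test_threshold_monotonicity(self):
        """Raising the threshold moves outcomes monotonically toward
        balanced lethal, never backwards."""
        order = {OUTCOME_POLY_BOTH_VIABLE: 0, OUTCOME_HALF_LETHAL: 1,
                 OUTCOME_BALANCED_LETHAL: 2}
        rng = np.random.default_rng(7)
        for _ in range(200):
            waa, wbb = rng.uniform(0, 0.2, size=2)
            ranks = [order[classify_from_means(waa, wbb, t)]
                     for t in (0.001, 0.01, 0.1)]
            assert ranks == sorted(ranks)

    def test_monomorphic_rejected(self):
        pop = spec_pop([IndividualSpec(ARR_B, (), ARR_B)])
        with pytest.raises(ValueError):
            classify_outcome(pop)

    def test_balanced_lethal_fixture_classified(self):
        pop = aodsim.make_balanced_lethal_fixture(20)
        assert classify_outcome(pop) == OUTCOME_BALANCED_LETHAL

    def test_absent_class_scored_by_expected_pairing(self):
        """An all-AB population with a recessive lethal fixed within A is
        half-lethal: expected W_AA from pairing A haplotypes is 0."""
        muts = [(2_500_100, -1.0, 0.0)]
        inds = [IndividualSpec(ARR_A, (0,), ARR_B, ()) for _ in range(10)]
        pop = spec_pop(inds, muts)
        assert classify_outcome(pop) == OUTCOME_HALF_LETHAL
        assert expected_karyotype_fitness(pop, "AA") == 0.0
        assert expected_karyotype_fitness(pop, "BB") == 1.0


class TestAODProperties:
    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.0, 2.0), st.floats(0.01, 2.0), st.floats(0.0, 2.0))
    def test_aod_identities(self, waa, wab, wbb):
        """s' = min(s1', s2') and symmetry = |s1' - s2'| for any positive
        heterokaryotype mean; s' > 0 iff AB beats both homokaryotype means."""
        rec = compute_aod(KaryotypeFitnessSummary(waa, wab, wbb, 1, 1, 1))
        assert rec.sp == min(rec.s1p, rec.s2p)
        assert rec.symmetry == abs(rec.s1p - rec.s2p)
        assert (rec.sp > 0) == (wab > max(waa, wbb))

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0),
           st.floats(0.001, 0.5), st.floats(0.001, 0.5))
    def test_classifier_monotone_in_threshold(self, waa, wbb, t1, t2):
        order = {OUTCOME_POLY_BOTH_VIABLE: 0, OUTCOME_HALF_LETHAL: 1,
                 OUTCOME_BALANCED_LETHAL: 2}
        lo, hi = sorted((t1, t2))
        assert order[classify_from_means(waa, wbb, lo)] <= \
            order[classify_from_means(waa, wbb, hi)]


class TestMaskingProperty:
    def test_fixed_in_arrangement_recessives_never_touch_heterokaryotype(self):
        """With h=0, a mutation carried by every A haplotype changes W_AA but
        not W_AB or W_BB."""
        base_muts = [(2_500_100, -0.3, 0.0)]
        inds = [IndividualSpec(ARR_A, (0,), ARR_A, (0,)),
                IndividualSpec(ARR_A, (0,), ARR_B, ()),
                IndividualSpec(ARR_B, (), ARR_B, ())]
        s0 = karyotype_fitness_summary(spec_pop(inds, base_muts))
        # add a second mutation private to (and fixed within) the A class
        muts2 = base_muts + [(3_000_100, -0.4, 0.0)]
        inds2 = [IndividualSpec(ARR_A, (0, 1), ARR_A, (0, 1)),
                 IndividualSpec(ARR_A, (0, 1), ARR_B, ()),
                 IndividualSpec(ARR_B, (), ARR_B, ())]
        s1 = karyotype_fitness_summary(spec_pop(inds2, muts2))
        assert s1.W_AA < s0.W_AA
        assert s1.W_AB == s0.W_AB
        assert s1.W_BB == s0.W_BB


class TestMutationsPerArrangement:
    def test_all_clean(self):
        pop = spec_pop([IndividualSpec(ARR_A, (), ARR_B)])
        assert mutations_per_arrangement(pop, (0, 20_000_000)) == (0.0, 0.0)

    def test_hand_means(self):
        muts = [(2_500_100, -0.1, 0.0), (3_000_100, -0.2, 0.0)]
        pop = spec_pop([IndividualSpec(ARR_A, (0,), ARR_A, (0, 1)),
                        IndividualSpec(ARR_B, (), ARR_B, ())], muts)
        mean_A, mean_B = mutations_per_arrangement(pop, (2_500_000, 7_500_000))
        assert mean_A == pytest.approx(1.5)
        assert mean_B == 0.0

    def test_region_and_sign_filters(self):
        # one deleterious mutation outside the region, one beneficial inside:
        # neither counts toward the deleterious region burden
        muts = [(100, -0.1, 0.0), (2_500_100, 0.05, 0.5)]
        pop = spec_pop([IndividualSpec(ARR_A, (0, 1), ARR_A, ())], muts)
        mean_A, mean_B = mutations_per_arrangement(pop, (2_500_000, 7_500_000))
        assert mean_A == 0.0
        assert math.isnan(mean_B)


class TestInvasionTiles:
    def test_all_invade(self):
        df = pd.DataFrame({"aod": np.full(30, 0.02), "symmetry": np.full(30, 0.001),
                           "invaded": True})
        tiles = bin_invasion_by_aod_symmetry(df)
        assert len(tiles) == 1 and tiles["invasion_prob"].iloc[0] == 1.0

    def test_direct_ratio(self):
        df = pd.DataFrame({"aod": np.full(40, 0.002), "symmetry": np.full(40, 0.001),
                           "invaded": [True] * 10 + [False] * 30})
        tiles = bin_invasion_by_aod_symmetry(df)
        assert tiles["invasion_prob"].iloc[0] == pytest.approx(0.25)

    def test_sparse_tiles_suppressed(self):
        df = pd.DataFrame({"aod": np.full(20, 0.002), "symmetry": np.full(20, 0.001),
                           "invaded": True})
        assert len(bin_invasion_by_aod_symmetry(df)) == 0  # n must exceed 20
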
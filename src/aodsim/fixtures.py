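"""Hand-specifiable synthetic populations for testing every analysis stage
without running evolution.

Fixtures build their own fresh mutation catalogs, so injected mutations never
collide with evolved ones.  Positions default to the allelic-content segments
inside the supergene region of the standard genome layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .burnin import BurninState
from .genome_model import GenomeMap, SimulationConfig, build_genome_map
from .wf_engine import (
    ARR_A,
    ARR_B,
    Haplotype,
    Individual,
    MutationCatalog,
    Population,
    individual_fitness,
)

__all__ = [
    "FixtureSpec",
    "IndividualSpec",
    "make_population",
    "make_balanced_lethal_fixture",
    "make_divergent_pair",
    "supergene_segment_positions",
]


@dataclass(frozen=True)
class IndividualSpec:
    """One diploid: arrangement labels plus indices into the fixture's
    mutation list for each haplotype."""

    arr1: int
    muts1: tuple[int, ...] = ()
    arr2: int = ARR_B
    muts2: tuple[int, ...] = ()


@dataclass
class FixtureSpec:
    """Deterministic description of a population.

    ``mutations`` is a list of (pos, s, h) triples; haplotype mutation lists
    and the fixed registry reference them by index.
    """

    label: str = "P1"
    individuals: list[IndividualSpec] = field(default_factory=list)
    mutations: list[tuple[int, float, float]] = field(default_factory=list)
    fixed: tuple[int, ...] = ()
    generation: int = 0
    gmap: GenomeMap | None = None


def _validate_positions(spec: FixtureSpec) -> None:
    if spec.gmap is None:
        return
    for pos, _, _ in spec.mutations:
        if not any(lo <= pos < hi for lo, hi in spec.gmap.segments):
            raise ValueError(f"mutation position {pos} lies outside every allelic segment")


def make_population(spec: FixtureSpec,
                    catalog: MutationCatalog | None = None) -> Population:
    """Build the exact population described by ``spec`` (fitness caches
    computed)."""
    positions = [m[0] for m in spec.mutations]
    if len(set(positions)) != len(positions):
        raise ValueError("fixture mutation positions must be unique")
    _validate_positions(spec)
    if catalog is None:
        catalog = MutationCatalog(capacity=max(1, len(spec.mutations)))
    ids = []
    for pos, s, h in spec.mutations:
        (mid,) = catalog.add_batch(np.array([pos], dtype=np.int64),
                                   np.array([s]), h, 0, spec.generation)
        ids.append(int(mid))
    ids = np.array(ids, dtype=np.int64)

    def hap(arr: int, idxs: tuple[int, ...]) -> Haplotype:
        if any(i >= len(spec.mutations) for i in idxs):
            raise ValueError("haplotype references a mutation index outside the fixture list")
        m = ids[list(idxs)]
        order = np.argsort(catalog.pos[m], kind="stable")
        return Haplotype(arr, m[order])

    individuals = []
    for ind_spec in spec.individuals:
        ind = Individual(hap(ind_spec.arr1, ind_spec.muts1),
                         hap(ind_spec.arr2, ind_spec.muts2))
        ind.fitness = individual_fitness(ind, catalog)
        individuals.append(ind)
    fixed_registry = {int(ids[i]) for i in spec.fixed}
    return Population(spec.label, individuals, catalog, spec.generation, fixed_registry)


def supergene_segment_positions(gmap: GenomeMap, n: int, offset: int = 0) -> list[int]:
    """``n`` distinct positions spread over the allelic segments lying inside
    the inversion interval."""
    lo, hi = gmap.inversion
    inner = [(a, b) for a, b in gmap.segments if a >= lo and b <= hi]
    if not inner:
        raise ValueError("no allelic segment lies inside the inversion")
    out = []
    for i in range(n):
        seg = inner[i % len(inner)]
        pos = seg[0] + offset + (i // len(inner))
        if pos >= seg[1]:
            raise ValueError("too many fixture mutations for the segment layout")
        out.append(pos)
    return out


def make_balanced_lethal_fixture(N: int, load_s: float = -1.0,
                                 config: SimulationConfig | None = None) -> Population:
    """All-heterokaryotype population in which each arrangement carries its own
    recessive lethal set: expected homokaryotype fitness < 0.01, heterokaryotype
    fitness 1.

    Every A haplotype carries one shared set of fully recessive mutations of
    effect ``load_s``; every B haplotype carries a disjoint set.  The number of
    mutations per set is the smallest k with (1 + load_s)^k < 0.01.
    """
    if N % 2:
        raise ValueError("N must be even")
    if not -1.0 <= load_s < 0.0:
        raise ValueError("load_s must lie in [-1, 0)")
    cfg = config or SimulationConfig()
    gmap = build_genome_map(cfg)
    if load_s == -1.0:
        k = 1
    else:
        k = max(1, math.ceil(math.log(0.009) / math.log(1.0 + load_s)))
    pos = supergene_segment_positions(gmap, 2 * k)
    mutations = [(p, load_s, 0.0) for p in pos]
    set_A = tuple(range(k))
    set_B = tuple(range(k, 2 * k))
    individuals = [IndividualSpec(ARR_A, set_A, ARR_B, set_B) for _ in range(N)]
    spec = FixtureSpec(label="P1", individuals=individuals, mutations=mutations,
                       generation=1, gmap=gmap)
    return make_population(spec)


def make_divergent_pair(n_private_fixed_1: int, n_private_fixed_2: int,
                        s_each: float,
                        config: SimulationConfig | None = None) -> BurninState:
    """Two monomorphic, mutation-free populations whose fixed registries hold
    the stated numbers of private recessive deleterious mutations of effect
    ``s_each``, placed in the supergene region.

    After :func:`aodsim.introgression.admix`, expected AOD has the closed form
    s1' = 1 - (1 + s)^k2 and s2' = 1 - (1 + s)^k1 under full recessivity
    (each homokaryotype is homozygous for its own arrangement's private set).
    """
    if min(n_private_fixed_1, n_private_fixed_2) < 0:
        raise ValueError("counts must be >= 0")
    if s_each >= 0:
        raise ValueError("s_each must be negative (deleterious)")
    cfg = config or SimulationConfig()
    gmap = build_genome_map(cfg)
    catalog = MutationCatalog()
    k1, k2 = n_private_fixed_1, n_private_fixed_2
    pos = supergene_segment_positions(gmap, k1 + k2)
    ids1 = catalog.add_batch(np.array(pos[:k1], dtype=np.int64),
                             np.full(k1, s_each), 0.0, 0, 0) if k1 else np.empty(0, np.int64)
    ids2 = catalog.add_batch(np.array(pos[k1:], dtype=np.int64),
                             np.full(k2, s_each), 0.0, 1, 0) if k2 else np.empty(0, np.int64)

    def pop(label: str, arr: int, fixed_ids: np.ndarray) -> Population:
        individuals = []
        for _ in range(cfg.N_BI):
            ind = Individual(Haplotype(arr), Haplotype(arr))
            ind.fitness = 1.0
            individuals.append(ind)
        return Population(label, individuals, catalog, cfg.T_BI,
                          {int(i) for i in fixed_ids})

    return BurninState(pop("P1", ARR_B, ids1), pop("P2", ARR_A, ids2), cfg,
                       burnin_id="fixture")
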
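"""Core forward-time machinery.

Multiplicative fitness over selected mutations, meiosis with inversion-aware
recombination (crossovers suppressed inside the inversion in heterokaryotypes,
gene conversion active everywhere), de novo mutation, and one-generation
Wright-Fisher updates with fitness-proportional parent sampling.

Haplotypes are arrangement labels plus position-sorted integer arrays of
mutation ids; mutations live in an append-only catalog shared by all
haplotypes of a simulation (id = catalog row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    GenomeMap,
    Mutation,
    SimulationConfig,
    sample_beneficial_effect,
    sample_deleterious_effect,
    sample_gc_tract_length,
)

__all__ = [
    "ARR_B",
    "ARR_A",
    "ExtinctionError",
    "MutationCatalog",
    "Haplotype",
    "Individual",
    "Population",
    "individual_fitness",
    "karyotype",
    "meiosis",
    "next_generation",
    "prune_fixed",
    "arrangement_frequency",
]

ARR_B = 0  # standard arrangement (P1 origin)
ARR_A = 1  # inverted arrangement (P2 origin)

_EMPTY = np.empty(0, dtype=np.int64)


class ExtinctionError(RuntimeError):
    """Raised when every individual in a population has fitness zero."""


class MutationCatalog:
    """Append-only store of mutations; the id of a mutation is its row index.

    Positions are unique catalog-wide (infinite-sites): proposed positions
    colliding with an occupied site are resampled by the caller via
    :meth:`draw_positions`.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self.n = 0
        self._pos = np.empty(capacity, dtype=np.int64)
        self._s = np.empty(capacity, dtype=np.float64)
        self._h = np.empty(capacity, dtype=np.float64)
        self._origin_pop = np.empty(capacity, dtype=np.int8)
        self._origin_gen = np.empty(capacity, dtype=np.int64)
        self._occupied: set[int] = set()

    def __len__(self) -> int:
        return self.n

    def _grow(self, extra: int) -> None:
        need = self.n + extra
        cap = self._pos.size
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in ("_pos", "_s", "_h", "_origin_pop", "_origin_gen"):
            old = getattr(self, name)
            new = np.empty(cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    @property
    def pos(self) -> np.ndarray:
        return self._pos[: self.n]

    @property
    def s(self) -> np.ndarray:
        return self._s[: self.n]

    @property
    def h(self) -> np.ndarray:
        return self._h[: self.n]

    @property
    def origin_pop(self) -> np.ndarray:
        return self._origin_pop[: self.n]

    @property
    def origin_gen(self) -> np.ndarray:
        return self._origin_gen[: self.n]

    def add_batch(self, positions: np.ndarray, s: np.ndarray, h: float,
                  origin_pop: int, origin_gen: int) -> np.ndarray:
        """Register new mutations; returns their ids."""
        k = len(positions)
        if k == 0:
            return _EMPTY
        if np.any(s == 0.0):
            raise ValueError("selection coefficients must be non-zero")
        self._grow(k)
        lo, hi = self.n, self.n + k
        self._pos[lo:hi] = positions
        self._s[lo:hi] = s
        self._h[lo:hi] = h
        self._origin_pop[lo:hi] = origin_pop
        self._origin_gen[lo:hi] = origin_gen
        self._occupied.update(int(p) for p in positions)
        self.n = hi
        return np.arange(lo, hi, dtype=np.int64)

    def get(self, mut_id: int) -> Mutation:
        if not 0 <= mut_id < self.n:
            raise KeyError(f"unknown mutation id {mut_id}")
        return Mutation(
            id=int(mut_id),
            pos=int(self._pos[mut_id]),
            s=float(self._s[mut_id]),
            h=float(self._h[mut_id]),
            origin_pop=int(self._origin_pop[mut_id]),
            origin_gen=int(self._origin_gen[mut_id]),
        )

    def check_ids(self, ids: np.ndarray) -> None:
        if ids.size and (ids.min() < 0 or ids.max() >= self.n):
            raise KeyError("haplotype references mutation ids missing from the catalog")

    def draw_positions(self, rng: np.random.Generator, gmap: GenomeMap,
                       segment_len: int, k: int) -> np.ndarray:
        """Sample ``k`` unoccupied positions uniformly over the segment union."""
        starts = gmap.segment_starts()
        out: list[int] = []
        seen = self._occupied
        while len(out) < k:
            idx = rng.integers(0, len(starts))
            p = int(starts[idx]) + int(rng.integers(0, segment_len))
            if p not in seen:
                seen.add(p)  # reserve immediately so one batch cannot collide
                out.append(p)
        return np.array(out, dtype=np.int64)


@dataclass
class Haplotype:
    """One gamete: arrangement label and position-sorted mutation ids."""

    arrangement: int
    muts: np.ndarray = field(default_factory=lambda: _EMPTY.copy())

    def copy(self) -> "Haplotype":
        return Haplotype(self.arrangement, self.muts.copy())


@dataclass
class Individual:
    hap1: Haplotype
    hap2: Haplotype
    fitness: float = 1.0


@dataclass
class Population:
    """N diploid individuals plus the registry of mutations fixed (and pruned)
    within this population."""

    label: str
    individuals: list[Individual]
    catalog: MutationCatalog
    generation: int = 0
    fixed_registry: set[int] = field(default_factory=set)

    @property
    def N(self) -> int:
        return len(self.individuals)

    def haplotypes(self):
        for ind in self.individuals:
            yield ind.hap1
            yield ind.hap2

    def fitnesses(self) -> np.ndarray:
        return np.array([ind.fitness for ind in self.individuals])

    def mean_fitness(self) -> float:
        return float(self.fitnesses().mean())


def _hom_het(m1: np.ndarray, m2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the union of two id arrays into homozygous and heterozygous ids."""
    if m1.size == 0 and m2.size == 0:
        return _EMPTY, _EMPTY
    both = np.concatenate([m1, m2])
    both.sort()
    dup = both[1:] == both[:-1]
    hom = both[:-1][dup]
    single = np.ones(both.size, dtype=bool)
    single[:-1][dup] = False
    single[1:][dup] = False
    return hom, both[single]


def individual_fitness(ind: Individual, catalog: MutationCatalog) -> float:
    """Multiplicative fitness relative to a mutation-free genotype.

    w = prod over homozygous sites (1 + s) * prod over heterozygous sites
    (1 + h*s), floored at 0 (any non-positive factor is lethal).
    """
    m1, m2 = ind.hap1.muts, ind.hap2.muts
    if m1.size == 0 and m2.size == 0:
        return 1.0
    both = np.concatenate([m1, m2])
    both.sort()
    if both[0] < 0 or both[-1] >= catalog.n:
        raise KeyError("haplotype references mutation ids missing from the catalog")
    s = catalog._s[both]
    dup = both[1:] == both[:-1]
    # heterozygous factor everywhere, then fix up homozygous pairs:
    # first of a pair carries (1+s), second is neutralized.
    fac = 1.0 + catalog._h[both] * s
    if dup.any():
        first = np.flatnonzero(dup)
        fac[first] = 1.0 + s[first]
        fac[first + 1] = 1.0
    if np.any(fac <= 0.0):
        return 0.0
    return max(float(np.prod(fac)), 0.0)


def karyotype(ind: Individual) -> str:
    """AA (both inverted), BB (both standard) or AB."""
    a = (ind.hap1.arrangement == ARR_A) + (ind.hap2.arrangement == ARR_A)
    return ("BB", "AB", "AA")[a]


def _draw_crossovers(rng: np.random.Generator, gmap: GenomeMap, rho: float,
                     heterokaryotype: bool) -> np.ndarray:
    """Crossover breakpoints (sorted, bp scale, excluding the obligate
    chromosome-boundary assortment point).

    In heterokaryotypes the inversion interval carries zero crossover rate:
    breakpoints are drawn uniformly on the genome minus the inversion, with
    the total rate reduced accordingly.
    """
    L = gmap.L
    if heterokaryotype:
        lo, hi = gmap.inversion
        L_eff = L - (hi - lo)
        k = rng.poisson(rho * L_eff)
        u = rng.random(k) * L_eff
        bp = np.where(u < lo, u, u + (hi - lo))
    else:
        k = rng.poisson(rho * L)
        bp = rng.random(k) * L
    bp.sort()
    return bp


def _draw_gc_tracts(rng: np.random.Generator, gmap: GenomeMap,
                    gamma_gc: float, lambda_gc: float) -> tuple[np.ndarray, np.ndarray]:
    """Gene-conversion tracts [start, start+len); returns (sorted starts, sorted ends)."""
    n = rng.poisson(gamma_gc * gmap.L)
    if n == 0:
        return _EMPTY.astype(float), _EMPTY.astype(float)
    starts = rng.random(n) * gmap.L
    lengths = sample_gc_tract_length(rng, lambda_gc, size=n)
    ends = starts + lengths
    return np.sort(starts), np.sort(ends)


def meiosis(parent: Individual, gmap: GenomeMap, config: SimulationConfig,
            rng: np.random.Generator, catalog: MutationCatalog,
            origin_pop: int, generation: int,
            beneficial: bool = False) -> Haplotype:
    """Produce one gamete from ``parent``.

    Crossover breakpoint count ~ Poisson(rho * permitted length); an obligate
    free-assortment point at the chromosome boundary fires with probability
    1/2.  Gene conversion initiates at rate gamma per bp anywhere (including
    inside the inversion in heterokaryotypes); each tract copies the
    homologous chromatid's content over [x, x+len) without changing the
    arrangement label.  De novo deleterious (and optionally beneficial)
    mutations are appended at Poisson per-gamete rates.
    """
    h1, h2 = parent.hap1, parent.hap2
    het = h1.arrangement != h2.arrangement
    bp = _draw_crossovers(rng, gmap, config.rho, het)
    if rng.random() < 0.5:
        bp = np.concatenate([bp, (float(gmap.chr_boundary),)])
        bp.sort()
    gc_starts, gc_ends = _draw_gc_tracts(rng, gmap, config.gamma_gc, config.lambda_gc)
    c0 = int(rng.integers(0, 2))

    n1 = h1.muts.size
    pos_all = catalog._pos[np.concatenate([h1.muts, h2.muts])]
    src = np.full(pos_all.shape, c0, dtype=np.int64)
    if bp.size:
        src += bp.searchsorted(pos_all, side="right")
    if gc_starts.size:
        src += (gc_starts.searchsorted(pos_all, side="right")
                - gc_ends.searchsorted(pos_all, side="right"))
    src &= 1
    keep1 = src[:n1] == 0
    keep2 = src[n1:] == 1
    take1 = h1.muts[keep1]
    take2 = h2.muts[keep2]

    # Arrangement follows the chromatid carrying the inversion after crossover
    # resolution only (gene conversion never moves the label).  In AB parents
    # no crossover falls inside the inversion, so any interior point works.
    inv_mid = (gmap.inversion[0] + gmap.inversion[1]) / 2.0
    arr_src = (c0 + int(bp.searchsorted(inv_mid, side="right"))) % 2
    arrangement = h1.arrangement if arr_src == 0 else h2.arrangement

    # De novo mutations.
    n_del = rng.poisson(config.gamete_del_rate())
    n_ben = rng.poisson(config.gamete_ben_rate()) if beneficial else 0
    new_ids = _EMPTY
    new_pos = _EMPTY
    if n_del or n_ben:
        k = n_del + n_ben
        positions = catalog.draw_positions(rng, gmap, config.segment_len, k)
        s = np.empty(k)
        h = np.empty(k)
        if n_del:
            s[:n_del] = sample_deleterious_effect(rng, config, size=n_del)
            h[:n_del] = config.h_del
        if n_ben:
            s[n_del:] = sample_beneficial_effect(rng, config, size=n_ben)
            h[n_del:] = config.h_ben
        ids_d = catalog.add_batch(positions[:n_del], s[:n_del], config.h_del,
                                  origin_pop, generation) if n_del else _EMPTY
        ids_b = catalog.add_batch(positions[n_del:], s[n_del:], config.h_ben,
                                  origin_pop, generation) if n_ben else _EMPTY
        new_ids = np.concatenate([ids_d, ids_b])
        new_pos = positions

    ids = np.concatenate([take1, take2, new_ids])
    pos = np.concatenate([pos_all[:n1][keep1], pos_all[n1:][keep2], new_pos])
    order = np.argsort(pos)
    return Haplotype(arrangement, ids[order])


def next_generation(pop: Population, N_next: int, config: SimulationConfig,
                    gmap: GenomeMap, rng: np.random.Generator,
                    beneficial: bool = False,
                    origin_pop: int | None = None) -> Population:
    """One Wright-Fisher generation: fitness-proportional parent sampling with
    replacement (selfing allowed), one meiosis per parent per offspring."""
    w = pop.fitnesses()
    total = w.sum()
    if total <= 0.0:
        raise ExtinctionError(
            f"population {pop.label} extinct at generation {pop.generation}")
    p = w / total
    gen = pop.generation + 1
    if origin_pop is None:
        from .genome_model import ORIGIN_P1, ORIGIN_P2, ORIGIN_POST
        origin_pop = {"P1": ORIGIN_P1, "P2": ORIGIN_P2}.get(pop.label, ORIGIN_POST)
    parents = rng.choice(pop.N, size=2 * N_next, p=p)
    offspring: list[Individual] = []
    cat = pop.catalog
    for i in range(N_next):
        mother = pop.individuals[parents[2 * i]]
        father = pop.individuals[parents[2 * i + 1]]
        g1 = meiosis(mother, gmap, config, rng, cat, origin_pop, gen, beneficial)
        g2 = meiosis(father, gmap, config, rng, cat, origin_pop, gen, beneficial)
        ind = Individual(g1, g2)
        ind.fitness = individual_fitness(ind, cat)
        offspring.append(ind)
    return Population(pop.label, offspring, cat, gen, set(pop.fixed_registry))


def prune_fixed(pop: Population) -> Population:
    """Move mutations present on all 2N haplotypes to the fixed registry and
    strip them from every haplotype (in place).

    Relative fitnesses are unchanged by pruning; cached absolute fitnesses are
    recomputed against the new mutation-free reference.
    """
    hap_arrays = [h.muts for h in pop.haplotypes()]
    if not hap_arrays:
        return pop
    allm = np.concatenate(hap_arrays)
    if allm.size == 0:
        return pop
    ids, counts = np.unique(allm, return_counts=True)
    fixed = ids[counts == 2 * pop.N]
    if fixed.size == 0:
        return pop
    fixed_set = set(int(i) for i in fixed)
    pop.fixed_registry.update(fixed_set)
    for ind in pop.individuals:
        for hap in (ind.hap1, ind.hap2):
            hap.muts = hap.muts[~np.isin(hap.muts, fixed)]
        ind.fitness = individual_fitness(ind, pop.catalog)
    return pop


def arrangement_frequency(pop: Population) -> float:
    """Frequency of the inverted (A) arrangement among the 2N haplotypes."""
    n_a = sum(1 for h in pop.haplotypes() if h.arrangement == ARR_A)
    return n_a / (2 * pop.N)
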
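"""Post-divergence stage: bottleneck, single-migrant admixture, and the
post-admixture evolution of the focal population P1.

The polymorphic period starts at generation 1 with the migration of one
randomly chosen P2 individual into the (already bottlenecked) P1.  From then
on only P1 is followed; beneficial mutations occur at a rate 1000x below the
deleterious rate.  A replicate ends when the inverted arrangement fixes or is
lost, when the population goes extinct, or at the generation cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (
    GenomeMap,
    SimulationConfig,
    build_genome_map,
    outcome_checkpoints,
    sampling_grid,
)
from .stats import compute_aod, karyotype_fitness_summary, mutations_per_arrangement, population_aod, classify_outcome
from .wf_engine import (
    ARR_A,
    ExtinctionError,
    Population,
    arrangement_frequency,
    next_generation,
    prune_fixed,
)

__all__ = [
    "ReplicateResult",
    "bottleneck",
    "admix",
    "run_post_admixture",
    "invasion_success",
    "run_replicate",
    "timeseries_frame",
]

STATUS_LOST = "LOST"
STATUS_FIXED = "FIXED"
STATUS_POLY = "POLYMORPHIC_AT_TMAX"
STATUS_EXTINCT = "EXTINCT"

_PRUNE_EVERY = 5


@dataclass
class ReplicateResult:
    replicate_id: str
    burnin_id: str
    seed: int | None
    status: str
    end_generation: int
    invasion: bool
    timeseries: list[dict] = field(default_factory=list)
    outcome_at: dict[int, str] = field(default_factory=dict)

    def timeseries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.timeseries)


def bottleneck(pop: Population, N_post: int, rng: np.random.Generator) -> Population:
    """Instant decline to ``N_post`` individuals sampled uniformly without
    replacement (applied to P1 immediately before admixture)."""
    if N_post > pop.N:
        raise ValueError(f"N_post={N_post} exceeds population size {pop.N}")
    idx = rng.choice(pop.N, size=N_post, replace=False)
    individuals = [pop.individuals[i] for i in idx]
    return Population(pop.label, individuals, pop.catalog, pop.generation,
                      set(pop.fixed_registry))


def admix(P1: Population, P2: Population, rng: np.random.Generator) -> Population:
    """One uniformly chosen P2 individual replaces one uniformly chosen P1
    resident; generation counter is set to 1 (the migration generation).

    Mutations fixed privately in either population re-materialize as
    segregating sites in the merged context: every resident haplotype gains
    P1's private fixed set, the migrant's haplotypes gain P2's, and mutations
    fixed in both populations remain pruned (they are invisible to relative
    fitness).
    """
    if P1.catalog is not P2.catalog:
        raise ValueError("populations must share a mutation catalog")
    cat = P1.catalog
    private1 = np.array(sorted(P1.fixed_registry - P2.fixed_registry), dtype=np.int64)
    private2 = np.array(sorted(P2.fixed_registry - P1.fixed_registry), dtype=np.int64)
    shared = P1.fixed_registry & P2.fixed_registry

    def rematerialize(hap_muts: np.ndarray, extra: np.ndarray) -> np.ndarray:
        if extra.size == 0:
            return hap_muts.copy()
        ids = np.concatenate([hap_muts, extra])
        order = np.argsort(cat.pos[ids], kind="stable")
        return ids[order]

    victim = int(rng.integers(0, P1.N))
    migrant_idx = int(rng.integers(0, P2.N))
    individuals = []
    from .wf_engine import Haplotype, Individual, individual_fitness

    for i, ind in enumerate(P1.individuals):
        if i == victim:
            src = P2.individuals[migrant_idx]
            extra = private2
        else:
            src = ind
            extra = private1
        new = Individual(
            Haplotype(src.hap1.arrangement, rematerialize(src.hap1.muts, extra)),
            Haplotype(src.hap2.arrangement, rematerialize(src.hap2.muts, extra)),
        )
        new.fitness = individual_fitness(new, cat)
        individuals.append(new)
    return Population("P1", individuals, cat, generation=1, fixed_registry=set(shared))


def _record_row(pop: Population, gmap: GenomeMap,
                rng: np.random.Generator) -> dict:
    summary, aod = population_aod(pop, fallback=True, rng=rng)
    n_mut_A, n_mut_B = mutations_per_arrangement(pop, gmap.inversion)
    return {
        "generation": pop.generation,
        "freq_A": arrangement_frequency(pop),
        "W_AA": summary.W_AA,
        "W_AB": summary.W_AB,
        "W_BB": summary.W_BB,
        "n_AA": summary.n_AA,
        "n_AB": summary.n_AB,
        "n_BB": summary.n_BB,
        "s1p": aod.s1p,
        "s2p": aod.s2p,
        "sp": aod.sp,
        "symmetry": aod.symmetry,
        "mean_fitness": pop.mean_fitness(),
        "n_mut_A": n_mut_A,
        "n_mut_B": n_mut_B,
    }


def run_post_admixture(pop: Population, config: SimulationConfig,
                       rng: np.random.Generator,
                       gmap: GenomeMap | None = None,
                       beneficial: bool = True,
                       replicate_id: str = "r0", burnin_id: str = "",
                       seed: int | None = None, collect: bool = True) -> ReplicateResult:
    """Iterate Wright-Fisher generations from the admixed population (at
    generation 1) until fixation, loss, extinction or ``T_max``.

    Time series are recorded on the rescaled sampling grid; at the rescaled
    outcome checkpoints a still-polymorphic population is classified as
    viable-viable, half-lethal or balanced-lethal.
    """
    if gmap is None:
        gmap = build_genome_map(config)
    grid = set(sampling_grid(config))
    checkpoints = set(outcome_checkpoints(config))
    N = pop.N
    T_max = config.T_max
    timeseries: list[dict] = []
    outcome_at: dict[int, str] = {}
    status = STATUS_POLY
    prune_fixed(pop)
    if collect and pop.generation in grid:
        timeseries.append(_record_row(pop, gmap, rng))
    end_gen = pop.generation
    while pop.generation < T_max:
        try:
            pop = next_generation(pop, N, config, gmap, rng, beneficial=beneficial)
        except ExtinctionError:
            status = STATUS_EXTINCT
            end_gen = pop.generation + 1
            break
        end_gen = pop.generation
        freq = arrangement_frequency(pop)
        if freq == 0.0:
            status = STATUS_LOST
            break
        if freq == 1.0:
            status = STATUS_FIXED
            break
        sampled = collect and (pop.generation in grid or pop.generation in checkpoints)
        if sampled or pop.generation % _PRUNE_EVERY == 0:
            prune_fixed(pop)
        if collect and pop.generation in grid:
            timeseries.append(_record_row(pop, gmap, rng))
        if collect and pop.generation in checkpoints:
            outcome_at[pop.generation] = classify_outcome(
                pop, config.viability_threshold, rng)
    result = ReplicateResult(
        replicate_id=replicate_id, burnin_id=burnin_id, seed=seed,
        status=status, end_generation=end_gen,
        invasion=False, timeseries=timeseries, outcome_at=outcome_at,
    )
    result.invasion = invasion_success(result, N)
    return result


def invasion_success(result: ReplicateResult, N_post: int) -> bool:
    """The inverted arrangement invaded if it was still present in P1 after
    ``N_post`` generations (fixation before then counts; loss or extinction at
    or before then does not)."""
    if result.status in (STATUS_LOST, STATUS_EXTINCT):
        return result.end_generation > N_post
    return True


def run_replicate(state, N_post: int | None = None,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None,
                  config: SimulationConfig | None = None,
                  beneficial: bool = True,
                  replicate_id: str = "r0", collect: bool = True) -> ReplicateResult:
    """Convenience wrapper: clone a burn-in state, bottleneck P1, admix one
    migrant, and run the post-admixture period."""
    from .burnin import clone_burnin_state

    if rng is None:
        rng = np.random.default_rng(seed)
    work = clone_burnin_state(state)
    cfg = config if config is not None else work.config
    n_post = N_post if N_post is not None else cfg.N_post
    p1 = bottleneck(work.P1, n_post, rng)
    pop = admix(p1, work.P2, rng)
    return run_post_admixture(pop, cfg, rng, beneficial=beneficial,
                              replicate_id=replicate_id,
                              burnin_id=state.burnin_id, seed=seed, collect=collect)


def timeseries_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    """Flat TSV-ready table of all replicate time series."""
    frames = []
    for res in results:
        if not res.timeseries:
            continue
        df = res.timeseries_frame()
        df.insert(0, "replicate_id", res.replicate_id)
        df.insert(1, "burnin_id", res.burnin_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
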
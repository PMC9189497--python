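"""Burn-in stage: two isolated populations diverging under deleterious
mutation pressure.

P1 carries the standard arrangement (B), P2 the inverted arrangement (A);
since each population is monomorphic for its arrangement no heterokaryotype
exists during burn-in and the labels are inert.  Burn-in length equals the
divergence time between the populations.  Beneficial mutations are disabled
during burn-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    GenomeMap,
    ORIGIN_P1,
    ORIGIN_P2,
    SimulationConfig,
    build_genome_map,
)
from .snapshots import (
    clone_catalog,
    clone_population,
    compact_catalog,
    load_catalog,
    load_population,
    save_catalog,
    save_population,
)
from .stats import LoadSummary, compute_loads
from .wf_engine import (
    ARR_A,
    ARR_B,
    Haplotype,
    Individual,
    MutationCatalog,
    Population,
    next_generation,
    prune_fixed,
)

__all__ = [
    "BurninState",
    "run_burnin",
    "count_fixed_differences",
    "make_burnin_bank",
    "save_burnin_state",
    "load_burnin_state",
    "clone_burnin_state",
]

#: Pruning cadence (generations).  Delaying pruning leaves already-fixed
#: mutations in every genotype, which multiplies all fitnesses by a common
#: factor and leaves Wright-Fisher sampling unchanged; populations are always
#: pruned before any measurement.
PRUNE_EVERY = 5


@dataclass
class BurninState:
    """Both diverged populations plus provenance and a load summary."""

    P1: Population
    P2: Population
    config: SimulationConfig
    burnin_id: str = "bi000"
    seed: int | None = None
    summary: dict = field(default_factory=dict)

    @property
    def gmap(self) -> GenomeMap:
        return build_genome_map(self.config)


def _fresh_population(label: str, arrangement: int, N: int,
                      catalog: MutationCatalog) -> Population:
    individuals = [Individual(Haplotype(arrangement), Haplotype(arrangement))
                   for _ in range(N)]
    return Population(label, individuals, catalog)


def summarize_burnin(state: BurninState) -> dict:
    """Fixed-difference count and supergene-region load decomposition."""
    region = state.gmap.inversion
    loads = {
        "P1": compute_loads(state.P1, region, state.P2),
        "P2": compute_loads(state.P2, region, state.P1),
    }
    return {
        "fixed_differences": count_fixed_differences(state),
        "n_fixed_P1": len(state.P1.fixed_registry),
        "n_fixed_P2": len(state.P2.fixed_registry),
        "loads": loads,
    }


def run_burnin(config: SimulationConfig, rng: np.random.Generator,
               burnin_id: str = "bi000", seed: int | None = None,
               summarize: bool = True) -> BurninState:
    """Evolve P1 and P2 independently for ``T_BI`` generations from
    mutation-free founders, with beneficial mutations disabled.

    Both populations share one mutation-id namespace (a common catalog, which
    is compacted to the surviving mutations at the end) but no post-split
    mutation is ever shared between them.
    """
    gmap = build_genome_map(config)
    catalog = MutationCatalog()
    p1 = _fresh_population("P1", ARR_B, config.N_BI, catalog)
    p2 = _fresh_population("P2", ARR_A, config.N_BI, catalog)
    for t in range(config.T_BI):
        p1 = next_generation(p1, config.N_BI, config, gmap, rng,
                             beneficial=False, origin_pop=ORIGIN_P1)
        p2 = next_generation(p2, config.N_BI, config, gmap, rng,
                             beneficial=False, origin_pop=ORIGIN_P2)
        if (t + 1) % PRUNE_EVERY == 0:
            prune_fixed(p1)
            prune_fixed(p2)
    prune_fixed(p1)
    prune_fixed(p2)
    compact_catalog(catalog, [p1, p2])
    state = BurninState(p1, p2, config, burnin_id=burnin_id, seed=seed)
    if summarize:
        state.summary = summarize_burnin(state)
    return state


def count_fixed_differences(state: BurninState) -> int:
    """Mutations fixed in exactly one population (private fixed)."""
    return len(state.P1.fixed_registry ^ state.P2.fixed_registry)


def make_burnin_bank(config: SimulationConfig, n_burnins: int,
                     root_seed: int, out_dir: str | Path | None = None
                     ) -> list[BurninState]:
    """Independent burn-ins with recorded, reproducible seeds.

    The i-th burn-in uses the seed sequence (root_seed, i); with an ``out_dir``
    every state is persisted along with a manifest TSV.
    """
    if n_burnins < 1:
        raise ValueError("n_burnins must be >= 1")
    states = []
    for i in range(n_burnins):
        rng = np.random.default_rng(np.random.SeedSequence([root_seed, i]))
        state = run_burnin(config, rng, burnin_id=f"bi{i:03d}", seed=root_seed)
        states.append(state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, state in enumerate(states):
            save_burnin_state(state, out_dir / state.burnin_id)
            loads = state.summary["loads"]["P1"]
            rows.append({
                "burnin_id": state.burnin_id,
                "root_seed": root_seed,
                "index": i,
                "fixed_differences": state.summary["fixed_differences"],
                "n_fixed_P1": state.summary["n_fixed_P1"],
                "n_fixed_P2": state.summary["n_fixed_P2"],
                "supergene_drift_load_P1": loads.drift_load,
                "supergene_mutational_load_P1": loads.mutational_load,
                "supergene_segregation_load_P1": loads.segregation_load,
                "supergene_drift_fraction_P1": loads.drift_fraction,
            })
        pd.DataFrame(rows).to_csv(out_dir / "bank_manifest.tsv", sep="\t", index=False)
    return states


def save_burnin_state(state: BurninState, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_catalog(state.P1.catalog, directory / "catalog.tsv")
    save_population(state.P1, directory / "p1", write_catalog=False)
    save_population(state.P2, directory / "p2", write_catalog=False)
    from dataclasses import asdict

    meta = {
        "burnin_id": state.burnin_id,
        "seed": state.seed,
        "config": asdict(state.config),
    }
    (directory / "state.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_burnin_state(directory: str | Path) -> BurninState:
    directory = Path(directory)
    meta = json.loads((directory / "state.json").read_text())
    catalog = load_catalog(directory / "catalog.tsv")
    p1 = load_population(directory / "p1", catalog)
    p2 = load_population(directory / "p2", catalog)
    config = SimulationConfig(**meta["config"])
    state = BurninState(p1, p2, config, burnin_id=meta["burnin_id"],
                        seed=meta["seed"])
    state.summary = summarize_burnin(state)
    return state


def clone_burnin_state(state: BurninState) -> BurninState:
    """Deep copy so one persisted burn-in can seed many replicates."""
    cat = clone_catalog(state.P1.catalog)
    p1 = clone_population(state.P1, cat)
    p2 = clone_population(state.P2, cat)
    return BurninState(p1, p2, state.config, state.burnin_id, state.seed,
                       dict(state.summary))
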
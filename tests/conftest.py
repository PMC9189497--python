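"""Shared fixtures.

Expensive simulation products (burn-in banks, the desk-scale experiment
block) are session-scoped so that the acceptance-level checks and the
module-level checks reuse the same runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import aodsim
from aodsim.burnin import run_burnin
from aodsim.experiment import desk_scale_config, gc_off_transform, map_profile
from aodsim.introgression import run_replicate


@pytest.fixture(scope="session")
def default_config() -> aodsim.SimulationConfig:
    return aodsim.SimulationConfig()


@pytest.fixture(scope="session")
def default_map(default_config) -> aodsim.GenomeMap:
    return aodsim.build_genome_map(default_config)


@pytest.fixture(scope="session")
def desk_config() -> aodsim.SimulationConfig:
    return desk_scale_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_config() -> aodsim.SimulationConfig:
    """A very small, fast configuration for smoke-level evolution tests."""
    cfg = desk_scale_config()
    return dataclasses.replace(cfg, N_BI=10, T_BI=60, T_max=200)


@pytest.fixture(scope="session")
def short_burnin_bank(desk_config) -> list[aodsim.BurninState]:
    """Five desk-scale burn-ins at the default divergence time (T_BI=2000)."""
    states = []
    for i in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([101, i]))
        states.append(run_burnin(desk_config, rng, burnin_id=f"short{i}"))
    return states


@pytest.fixture(scope="session")
def long_burnin_bank(desk_config) -> list[aodsim.BurninState]:
    """Five desk-scale burn-ins at 2.5x the default divergence time."""
    cfg = dataclasses.replace(desk_config, T_BI=desk_config.T_BI * 5 // 2)
    states = []
    for i in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([202, i]))
        states.append(run_burnin(cfg, rng, burnin_id=f"long{i}"))
    return states


@pytest.fixture(scope="session")
def map_burnins() -> list[aodsim.BurninState]:
    """Two burn-ins at the outcome-map profile (1.5x mutation input)."""
    cfg = map_profile()
    states = []
    for i in range(3):
        rng = np.random.default_rng(np.random.SeedSequence([303, i]))
        states.append(run_burnin(cfg, rng, burnin_id=f"map{i}"))
    return states


# replicate counts per outcome-map cell: more power where the rare classes live
MAP_CELLS = (
    (False, 12, 75),  # (gc_on, N_post, n_replicates)
    (False, 50, 36),
    (True, 12, 24),
    (True, 50, 15),
)


@pytest.fixture(scope="session")
def map_block(map_burnins):
    """Desk-scale outcome-map experiment: replicate records and full results
    for four (gene conversion x population size) cells at h=0."""
    rows = []
    results = []
    for gc_on, N_post, n_reps in MAP_CELLS:
        for bi, state in enumerate(map_burnins):
            cfg = dataclasses.replace(state.config, N_post=N_post)
            if not gc_on:
                cfg = gc_off_transform(cfg)
            for rep in range(n_reps // len(map_burnins)):
                rng = np.random.default_rng(
                    np.random.SeedSequence([404, int(gc_on), N_post, bi, rep]))
                res = run_replicate(state, rng=rng, config=cfg,
                                    replicate_id=f"g{int(gc_on)}_n{N_post}_b{bi}_r{rep}")
                final = max(res.outcome_at) if res.outcome_at else None
                rows.append({
                    "gc_on": gc_on, "N_post": N_post, "burnin_id": state.burnin_id,
                    "status": res.status, "invaded": res.invasion,
                    "end_generation": res.end_generation,
                    "aod": res.timeseries[0]["sp"] if res.timeseries else np.nan,
                    "symmetry": res.timeseries[0]["symmetry"] if res.timeseries else np.nan,
                    "outcome_final": res.outcome_at[final] if final else "",
                    "outcome_mid": res.outcome_at.get(1000, ""),
                })
                results.append(res)
    import pandas as pd

    return pd.DataFrame(rows), results
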
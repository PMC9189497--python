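"""Full-block experiment orchestration.

The study design crosses two burn-in factors (burn-in length, dominance of
deleterious mutations) with two post-admixture factors (gene conversion
on/off, population size), reusing a bank of persisted burn-ins across
replicates.  Seeds derive from a root seed by a deterministic splitting rule,
so an entire block is bit-for-bit reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .burnin import BurninState
from .genome_model import SimulationConfig, outcome_checkpoints, rescale_config
from .introgression import (
    STATUS_EXTINCT,
    STATUS_FIXED,
    STATUS_LOST,
    STATUS_POLY,
    ReplicateResult,
    run_replicate,
)
from .stats import (
    OUTCOME_BALANCED_LETHAL,
    OUTCOME_HALF_LETHAL,
    OUTCOME_POLY_BOTH_VIABLE,
)

__all__ = [
    "Cell",
    "BlockDesign",
    "BlockResult",
    "gc_off_transform",
    "run_block",
    "outcome_table",
    "balanced_lethal_probability_vs_N",
    "outcome_persistence",
    "desk_scale_config",
]


def gc_off_transform(config: SimulationConfig) -> SimulationConfig:
    """Remove gene conversion, converting its rate into crossovers so the
    total recombination rate outside the supergene is unchanged."""
    if config.gamma_gc == 0:
        return config
    return replace(config, rho=config.rho + config.gamma_gc, gamma_gc=0.0)


def desk_scale_config(Q: int = 100, *, N_post: int | None = None,
                      **overrides) -> SimulationConfig:
    """Headline parameters reduced to desk scale.

    Population sizes and all durations shrink by ``Q`` and recombination rates
    grow by ``Q`` (an exact rescaling of the neutral transmission process, so
    N*rho*L and N*gamma*L are preserved), while the mutation rate and the
    fitness-effect distributions stay at their nominal per-generation values.

    A full diffusion rescale is impossible at this depth: multiplying gamma
    DFE draws by 100 turns most mutations into recessive lethals (1 + s <= 0)
    and a small population melts down, while multiplying the mutation rate
    instead saturates the drift load (homokaryotypes would already be
    inviable at admixture).  Keeping mu and the DFE nominal reproduces the
    study's burn-in state — drift-dominated supergene load with viable
    homokaryotypes — in a population 100x smaller, at the cost of stronger
    drift relative to selection and 100x lower diversity.

    Default: N_BI=25, T_BI=2000, N_post=25, T_max=2000; a burn-in pair takes
    seconds.
    """
    cfg = SimulationConfig(**overrides)
    cfg = replace(
        cfg,
        rho=cfg.rho * Q,
        gamma_gc=cfg.gamma_gc * Q,
        N_BI=cfg.N_BI // Q,
        N_post=max(2, cfg.N_post // Q),
        T_BI=cfg.T_BI // Q,
        T_max=cfg.T_max // Q,
        scale_Q=cfg.scale_Q * Q,  # keeps sampling grids and checkpoints proportional
    )
    if N_post is not None:
        cfg = replace(cfg, N_post=N_post)
    return cfg


def map_profile(**overrides) -> SimulationConfig:
    """Desk configuration for the outcome-map experiment (fate of long-lived
    polymorphisms).

    Starts from :func:`desk_scale_config` with two changes.  The deleterious
    and beneficial mutation rates are raised 1.5x so that the time for a
    sheltered arrangement to accumulate a lethal recessive load falls inside
    the simulated horizon, as it does at the study scale (degeneration over
    roughly half of the 200 000-generation cap); at nominal rates the desk
    degeneration timescale is 2-3x the horizon and no half-lethal or
    balanced-lethal state can be reached by T_max.  The burn-in runs at
    N_BI=50 for 4000 generations — the study's divergence time of 80 x N_BI —
    so that a post-admixture population of 50 (where purifying selection on
    exposed homokaryotypes still operates, N s-bar of order 1) is available
    as the protected large-population cell alongside small cells around
    N = 12.
    """
    cfg = desk_scale_config(**overrides)
    return replace(cfg, mu=cfg.mu * 1.5, beneficial_mu=cfg.beneficial_mu * 1.5,
                   N_BI=cfg.N_BI * 2, N_post=cfg.N_post * 2,
                   T_BI=cfg.T_BI * 2)


@dataclass(frozen=True)
class Cell:
    gc_on: bool
    h_del: float
    T_BI: int
    N_post: int

    def key(self) -> tuple:
        return (self.gc_on, self.h_del, self.T_BI, self.N_post)


@dataclass
class BlockDesign:
    """Factor levels (on whatever scale the bank's configs use) plus replicate
    counts.

    With ``restrict_extra_N`` (the study layout), population sizes outside the
    two extreme levels are only run with h=0 and gene conversion off.
    """

    gc_levels: tuple[bool, ...] = (True, False)
    h_levels: tuple[float, ...] = (0.0, 0.1)
    T_BI_levels: tuple[int, ...] = (2000, 5000)
    N_post_levels: tuple[int, ...] = (5, 25)
    n_replicates: int = 200
    restrict_extra_N: bool = True

    def cells(self) -> list[Cell]:
        out = []
        extreme = {min(self.N_post_levels), max(self.N_post_levels)}
        for gc, h, t, n in itertools.product(self.gc_levels, self.h_levels,
                                             self.T_BI_levels, self.N_post_levels):
            if self.restrict_extra_N and n not in extreme and (gc or h != 0.0):
                continue
            out.append(Cell(gc, h, t, n))
        return out


@dataclass
class BlockResult:
    records: pd.DataFrame
    results: list[ReplicateResult] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return outcome_table(self.records)


def _first_ts(res: ReplicateResult, col: str) -> float:
    return res.timeseries[0][col] if res.timeseries else math.nan


def run_block(design: BlockDesign, bank: dict[tuple[int, float], list[BurninState]],
              root_seed: int, beneficial: bool = True,
              keep_results: bool = False) -> BlockResult:
    """Execute every replicate of every design cell.

    ``bank`` maps (T_BI, h_del) to the burn-in states of that burn-in cell;
    a missing cell raises before any simulation starts.  Replicate seeds are
    SeedSequence([root_seed, cell_index, burnin_index, replicate_index]).
    """
    cells = design.cells()
    for cell in cells:
        if (cell.T_BI, cell.h_del) not in bank:
            raise KeyError(f"burn-in bank has no entry for T_BI={cell.T_BI}, h={cell.h_del}")
    rows = []
    kept: list[ReplicateResult] = []
    for ci, cell in enumerate(cells):
        states = bank[(cell.T_BI, cell.h_del)]
        n_per = max(1, design.n_replicates // len(states))
        for bi, state in enumerate(states):
            cfg = replace(state.config, N_post=cell.N_post)
            if not cell.gc_on:
                cfg = gc_off_transform(cfg)
            checkpoints = outcome_checkpoints(cfg)
            for rep in range(n_per):
                ss = np.random.SeedSequence([root_seed, ci, bi, rep])
                rng = np.random.default_rng(ss)
                res = run_replicate(state, rng=rng, config=cfg,
                                    beneficial=beneficial,
                                    replicate_id=f"c{ci}_b{bi}_r{rep}")
                row = {
                    "gc_on": cell.gc_on, "h_del": cell.h_del,
                    "T_BI": cell.T_BI, "N_post": cell.N_post,
                    "burnin_id": state.burnin_id,
                    "replicate_id": res.replicate_id,
                    "status": res.status,
                    "end_generation": res.end_generation,
                    "invaded": res.invasion,
                    "aod": _first_ts(res, "sp"),
                    "symmetry": _first_ts(res, "symmetry"),
                }
                for c in checkpoints:
                    row[f"outcome_{c}"] = res.outcome_at.get(c, "")
                row["outcome_final"] = res.outcome_at.get(checkpoints[-1], "") \
                    if checkpoints else ""
                rows.append(row)
                if keep_results:
                    kept.append(res)
    return BlockResult(pd.DataFrame(rows), kept)


def outcome_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell counts of terminal statuses and final outcome classes, plus the
    invasion rate."""
    keys = ["gc_on", "h_del", "T_BI", "N_post"]
    rows = []
    for cell_key, grp in records.groupby(keys):
        row = dict(zip(keys, cell_key))
        row["n"] = len(grp)
        for status in (STATUS_LOST, STATUS_FIXED, STATUS_EXTINCT, STATUS_POLY):
            row[f"n_{status}"] = int((grp["status"] == status).sum())
        for outcome in (OUTCOME_POLY_BOTH_VIABLE, OUTCOME_HALF_LETHAL,
                        OUTCOME_BALANCED_LETHAL):
            row[f"n_{outcome}"] = int((grp["outcome_final"] == outcome).sum())
        row["invasion_rate"] = float(grp["invaded"].mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)


def balanced_lethal_probability_vs_N(records: pd.DataFrame) -> pd.DataFrame:
    """P(balanced lethal at the end of the run | invasion) per burn-in and
    population size; NaN where a conditioning set is empty."""
    rows = []
    for (bi, n), grp in records.groupby(["burnin_id", "N_post"]):
        invaded = grp[grp["invaded"]]
        if len(invaded) == 0:
            p = math.nan
        else:
            p = float((invaded["outcome_final"] == OUTCOME_BALANCED_LETHAL).mean())
        rows.append({"burnin_id": bi, "N_post": n,
                     "n_invaded": len(invaded), "p_balanced_lethal": p})
    return pd.DataFrame(rows).sort_values(["burnin_id", "N_post"]).reset_index(drop=True)


def outcome_persistence(records: pd.DataFrame,
                        checkpoints: tuple[int, ...]) -> pd.DataFrame:
    """Transition fractions between outcome classes across checkpoints.

    For each ordered checkpoint pair (c1, c2) and each class at c1, the
    fraction of those replicates found in each class or terminal status at c2
    (a replicate that fixed, was lost or went extinct by c2 is counted under
    its terminal status).
    """
    rows = []
    for c1, c2 in itertools.combinations(checkpoints, 2):
        col1, col2 = f"outcome_{c1}", f"outcome_{c2}"
        at_c1 = records[records[col1] != ""]
        for cls, grp in at_c1.groupby(col1):
            end_states = grp.apply(
                lambda r: r[col2] if r[col2] != ""
                else (r["status"] if r["end_generation"] <= c2 else STATUS_POLY),
                axis=1)
            frac = end_states.value_counts(normalize=True)
            for to_cls, f in frac.items():
                rows.append({"from_checkpoint": c1, "to_checkpoint": c2,
                             "from_class": cls, "to_class": to_cls,
                             "fraction": float(f),
                             "n_from": len(grp)})
    return pd.DataFrame(rows)
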
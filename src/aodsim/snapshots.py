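"""Plain-text population snapshots.

A population serializes to JSON-lines (one individual per line: arrangement
pair plus the two mutation-id lists), a mutation-catalog TSV (id, pos, s, h,
origin_pop, origin_gen) and a small JSON meta file (label, generation, fixed
registry).  Round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .wf_engine import Haplotype, Individual, MutationCatalog, Population, individual_fitness

__all__ = [
    "save_catalog",
    "load_catalog",
    "save_population",
    "load_population",
    "compact_catalog",
]

CATALOG_COLUMNS = ["id", "pos", "s", "h", "origin_pop", "origin_gen"]


def save_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    df = pd.DataFrame({
        "id": np.arange(catalog.n, dtype=np.int64),
        "pos": catalog.pos,
        "s": catalog.s,
        "h": catalog.h,
        "origin_pop": catalog.origin_pop,
        "origin_gen": catalog.origin_gen,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_catalog(path: str | Path) -> MutationCatalog:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != CATALOG_COLUMNS:
        raise ValueError(f"unexpected catalog columns in {path}")
    if not np.array_equal(df["id"].to_numpy(), np.arange(len(df))):
        raise ValueError("catalog ids must be the contiguous range 0..n-1")
    cat = MutationCatalog(capacity=max(1, len(df)))
    if len(df):
        cat.add_batch(df["pos"].to_numpy(np.int64), df["s"].to_numpy(float),
                      0.0, 0, 0)
        cat._h[: cat.n] = df["h"].to_numpy(float)
        cat._origin_pop[: cat.n] = df["origin_pop"].to_numpy(np.int8)
        cat._origin_gen[: cat.n] = df["origin_gen"].to_numpy(np.int64)
    return cat


def save_population(pop: Population, prefix: str | Path,
                    write_catalog: bool = True) -> None:
    """Write ``<prefix>.jsonl``, ``<prefix>.meta.json`` and (optionally)
    ``<prefix>.catalog.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.jsonl", "w") as fh:
        for ind in pop.individuals:
            fh.write(json.dumps({
                "a": [int(ind.hap1.arrangement), int(ind.hap2.arrangement)],
                "m": [ind.hap1.muts.tolist(), ind.hap2.muts.tolist()],
            }) + "\n")
    meta = {
        "label": pop.label,
        "generation": pop.generation,
        "fixed_registry": sorted(int(i) for i in pop.fixed_registry),
    }
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta) + "\n")
    if write_catalog:
        save_catalog(pop.catalog, f"{prefix}.catalog.tsv")


def load_population(prefix: str | Path,
                    catalog: MutationCatalog | None = None) -> Population:
    prefix = Path(prefix)
    if catalog is None:
        catalog = load_catalog(f"{prefix}.catalog.tsv")
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    individuals: list[Individual] = []
    with open(f"{prefix}.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            h1 = Haplotype(rec["a"][0], np.array(rec["m"][0], dtype=np.int64))
            h2 = Haplotype(rec["a"][1], np.array(rec["m"][1], dtype=np.int64))
            ind = Individual(h1, h2)
            ind.fitness = individual_fitness(ind, catalog)
            individuals.append(ind)
    return Population(meta["label"], individuals, catalog, meta["generation"],
                      set(meta["fixed_registry"]))


def compact_catalog(catalog: MutationCatalog,
                    populations: list[Population]) -> MutationCatalog:
    """Drop extinct mutations and renumber ids.

    Keeps mutations still referenced by any haplotype or fixed registry of the
    given populations, rewrites haplotypes and registries in place, and
    returns the new catalog.
    """
    keep: set[int] = set()
    for pop in populations:
        keep.update(pop.fixed_registry)
        for hap in pop.haplotypes():
            keep.update(int(i) for i in hap.muts)
    old_ids = np.array(sorted(keep), dtype=np.int64)
    id_map = np.full(catalog.n, -1, dtype=np.int64)
    id_map[old_ids] = np.arange(old_ids.size)
    new = MutationCatalog(capacity=max(1, old_ids.size))
    if old_ids.size:
        new.add_batch(catalog.pos[old_ids], catalog.s[old_ids], 0.0, 0, 0)
        new._h[: new.n] = catalog.h[old_ids]
        new._origin_pop[: new.n] = catalog.origin_pop[old_ids]
        new._origin_gen[: new.n] = catalog.origin_gen[old_ids]
    for pop in populations:
        pop.catalog = new
        pop.fixed_registry = {int(id_map[i]) for i in pop.fixed_registry}
        for hap in pop.haplotypes():
            hap.muts = id_map[hap.muts]
    return new


def clone_population(pop: Population, catalog: MutationCatalog | None = None) -> Population:
    """Deep copy of a population (optionally onto a different catalog copy)."""
    cat = catalog if catalog is not None else pop.catalog
    individuals = []
    for ind in pop.individuals:
        new = Individual(ind.hap1.copy(), ind.hap2.copy(), ind.fitness)
        individuals.append(new)
    return Population(pop.label, individuals, cat, pop.generation,
                      set(pop.fixed_registry))


def clone_catalog(catalog: MutationCatalog) -> MutationCatalog:
    new = MutationCatalog(capacity=max(1, catalog.n))
    if catalog.n:
        new.add_batch(catalog.pos.copy(), catalog.s.copy(), 0.0, 0, 0)
        new._h[: new.n] = catalog.h
        new._origin_pop[: new.n] = catalog.origin_pop
        new._origin_gen[: new.n] = catalog.origin_gen
    return new
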
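"""Summary statistics for supergene polymorphism dynamics.

Associative overdominance (AOD) is measured from karyotype mean fitnesses as

    s1' = 1 - W_AA / W_AB,   s2' = 1 - W_BB / W_AB,   s' = min(s1', s2'),

where A is the inverted arrangement and B the standard one; positive s' means
the heterokaryotype is fitter than both homokaryotypes.  The symmetry of the
two load components is |s1' - s2'|.

Fitness load over a genomic region decomposes into a drift component (private
fixed deleterious mutations, re-exposed after admixture) and a mutational
component (segregating deleterious mutations), composed multiplicatively:
1 - L_seg = (1 - L_drift)(1 - L_mut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wf_engine import (
    ARR_A,
    ARR_B,
    Haplotype,
    Individual,
    MutationCatalog,
    Population,
    individual_fitness,
    karyotype,
)

__all__ = [
    "KaryotypeFitnessSummary",
    "AODRecord",
    "LoadSummary",
    "OUTCOME_POLY_BOTH_VIABLE",
    "OUTCOME_HALF_LETHAL",
    "OUTCOME_BALANCED_LETHAL",
    "karyotype_fitness_summary",
    "compute_aod",
    "population_aod",
    "expected_karyotype_fitness",
    "compute_loads",
    "classify_outcome",
    "classify_from_means",
    "mutations_per_arrangement",
    "bin_invasion_by_aod_symmetry",
]

OUTCOME_POLY_BOTH_VIABLE = "POLY_BOTH_VIABLE"
OUTCOME_HALF_LETHAL = "HALF_LETHAL"
OUTCOME_BALANCED_LETHAL = "BALANCED_LETHAL"


@dataclass(frozen=True)
class KaryotypeFitnessSummary:
    """Arithmetic mean fitness and count per karyotype class (NaN if absent)."""

    W_AA: float
    W_AB: float
    W_BB: float
    n_AA: int
    n_AB: int
    n_BB: int
    generation: int = 0


@dataclass(frozen=True)
class AODRecord:
    """AOD components at one sampled generation (NaN where undefined)."""

    s1p: float
    s2p: float
    sp: float
    symmetry: float
    generation: int = 0


@dataclass(frozen=True)
class LoadSummary:
    region: str
    drift_load: float
    mutational_load: float
    segregation_load: float
    drift_fraction: float


def karyotype_fitness_summary(pop: Population) -> KaryotypeFitnessSummary:
    """Mean individual fitness within each karyotype class present."""
    sums = {"AA": 0.0, "AB": 0.0, "BB": 0.0}
    counts = {"AA": 0, "AB": 0, "BB": 0}
    for ind in pop.individuals:
        k = karyotype(ind)
        sums[k] += ind.fitness
        counts[k] += 1

    def mean(k: str) -> float:
        return sums[k] / counts[k] if counts[k] else math.nan

    return KaryotypeFitnessSummary(
        W_AA=mean("AA"), W_AB=mean("AB"), W_BB=mean("BB"),
        n_AA=counts["AA"], n_AB=counts["AB"], n_BB=counts["BB"],
        generation=pop.generation,
    )


def compute_aod(summary: KaryotypeFitnessSummary) -> AODRecord:
    """AOD from karyotype means; undefined components propagate as NaN."""
    W_AB = summary.W_AB
    if not (W_AB and W_AB > 0) or math.isnan(W_AB):
        return AODRecord(math.nan, math.nan, math.nan, math.nan, summary.generation)
    s1p = 1.0 - summary.W_AA / W_AB if not math.isnan(summary.W_AA) else math.nan
    s2p = 1.0 - summary.W_BB / W_AB if not math.isnan(summary.W_BB) else math.nan
    if math.isnan(s1p) or math.isnan(s2p):
        sp = math.nan
        sym = math.nan
    else:
        sp = min(s1p, s2p)
        sym = abs(s1p - s2p)
    return AODRecord(s1p, s2p, sp, sym, summary.generation)


def expected_karyotype_fitness(pop: Population, kind: str,
                               rng: np.random.Generator | None = None,
                               max_exact_pairs: int = 256,
                               n_samples: int = 256) -> float:
    """Expected mean fitness of a karyotype class formed by random pairing of
    the standing haplotypes of the required arrangement(s).

    Used when a class is absent from the standing population (e.g. lethal
    homokaryotypes that never survive to adulthood).  All ordered pairs are
    enumerated when few; otherwise ``n_samples`` random pairs are drawn.
    """
    haps_A = [h for h in pop.haplotypes() if h.arrangement == ARR_A]
    haps_B = [h for h in pop.haplotypes() if h.arrangement == ARR_B]
    pools = {"AA": (haps_A, haps_A), "BB": (haps_B, haps_B), "AB": (haps_A, haps_B)}
    pool1, pool2 = pools[kind]
    if not pool1 or not pool2:
        return math.nan
    n_pairs = len(pool1) * len(pool2)
    cat = pop.catalog
    if n_pairs <= max_exact_pairs:
        pairs = [(h1, h2) for h1 in pool1 for h2 in pool2]
    else:
        if rng is None:
            rng = np.random.default_rng(n_pairs)
        i = rng.integers(0, len(pool1), size=n_samples)
        j = rng.integers(0, len(pool2), size=n_samples)
        pairs = [(pool1[a], pool2[b]) for a, b in zip(i, j)]
    total = 0.0
    for h1, h2 in pairs:
        total += individual_fitness(Individual(h1, h2), cat)
    return total / len(pairs)


def population_aod(pop: Population, fallback: bool = False,
                   rng: np.random.Generator | None = None
                   ) -> tuple[KaryotypeFitnessSummary, AODRecord]:
    """Karyotype summary and AOD for a population.

    With ``fallback=True``, class means that are undefined because the class is
    absent are replaced by expected random-pairing means (the only way the
    statistic exists immediately after admixture or once a homokaryotype is
    lethal)."""
    summary = karyotype_fitness_summary(pop)
    if fallback:
        vals = {"W_AA": summary.W_AA, "W_AB": summary.W_AB, "W_BB": summary.W_BB}
        for key, kind in (("W_AA", "AA"), ("W_AB", "AB"), ("W_BB", "BB")):
            if math.isnan(vals[key]):
                vals[key] = expected_karyotype_fitness(pop, kind, rng)
        summary = KaryotypeFitnessSummary(
            W_AA=vals["W_AA"], W_AB=vals["W_AB"], W_BB=vals["W_BB"],
            n_AA=summary.n_AA, n_AB=summary.n_AB, n_BB=summary.n_BB,
            generation=summary.generation,
        )
    return summary, compute_aod(summary)


def _region_fitness(ind: Individual, cat: MutationCatalog, lo: int, hi: int) -> float:
    """Fitness of an individual counting only mutations with lo <= pos < hi."""
    pos = cat.pos
    m1 = ind.hap1.muts
    m2 = ind.hap2.muts
    m1 = m1[(pos[m1] >= lo) & (pos[m1] < hi)] if m1.size else m1
    m2 = m2[(pos[m2] >= lo) & (pos[m2] < hi)] if m2.size else m2
    return individual_fitness(Individual(Haplotype(ind.hap1.arrangement, m1),
                                         Haplotype(ind.hap2.arrangement, m2)),
                              cat)


def compute_loads(pop: Population, region: tuple[int, int],
                  reference: Population | set[int] | None = None,
                  region_name: str = "supergene") -> LoadSummary:
    """Decompose the load of a genomic region for one population.

    mutational_load: 1 - mean fitness computed from segregating region
    mutations only.  drift_load: 1 - product of (1+s) over deleterious
    mutations fixed in this population but not in ``reference`` (the private
    fixed set that would re-segregate after admixture).  The two compose
    multiplicatively into segregation_load.
    """
    lo, hi = region
    cat = pop.catalog
    if pop.individuals:
        mean_w = float(np.mean([_region_fitness(ind, cat, lo, hi)
                                for ind in pop.individuals]))
    else:
        mean_w = 1.0
    mutational = min(max(1.0 - mean_w, 0.0), 1.0)

    if reference is None:
        ref_fixed: set[int] = set()
    elif isinstance(reference, Population):
        ref_fixed = reference.fixed_registry
    else:
        ref_fixed = reference
    private = np.array(sorted(pop.fixed_registry - ref_fixed), dtype=np.int64)
    if private.size:
        in_region = (cat.pos[private] >= lo) & (cat.pos[private] < hi)
        s = cat.s[private[in_region]]
        s = s[s < 0]
        prod = float(np.prod(1.0 + s)) if s.size else 1.0
        drift = min(max(1.0 - max(prod, 0.0), 0.0), 1.0)
    else:
        drift = 0.0

    segregation = 1.0 - (1.0 - drift) * (1.0 - mutational)
    fraction = drift / segregation if segregation > 0 else math.nan
    return LoadSummary(region_name, drift, mutational, segregation, fraction)


def classify_from_means(W_AA: float, W_BB: float, threshold: float = 0.01) -> str:
    """Outcome class from the two homokaryotype mean fitnesses."""
    if math.isnan(W_AA) or math.isnan(W_BB):
        raise ValueError("homokaryotype means undefined; supply expected-pairing values")
    dead_AA = W_AA < threshold
    dead_BB = W_BB < threshold
    if dead_AA and dead_BB:
        return OUTCOME_BALANCED_LETHAL
    if dead_AA or dead_BB:
        return OUTCOME_HALF_LETHAL
    return OUTCOME_POLY_BOTH_VIABLE


def classify_outcome(pop: Population, threshold: float = 0.01,
                     rng: np.random.Generator | None = None) -> str:
    """Classify a polymorphic population: both homokaryotypes viable, one
    inviable (half-lethal), or both inviable (balanced lethal).

    Realized class means are used where the class is present; an absent class
    is scored by the expected mean fitness of random within-arrangement
    haplotype pairings (a lethal class is absent from the standing population
    by definition)."""
    from .wf_engine import arrangement_frequency

    freq = arrangement_frequency(pop)
    if freq in (0.0, 1.0):
        raise ValueError("outcome classification requires a polymorphic population")
    summary = karyotype_fitness_summary(pop)
    W_AA = summary.W_AA
    W_BB = summary.W_BB
    if math.isnan(W_AA):
        W_AA = expected_karyotype_fitness(pop, "AA", rng)
    if math.isnan(W_BB):
        W_BB = expected_karyotype_fitness(pop, "BB", rng)
    return classify_from_means(W_AA, W_BB, threshold)


def mutations_per_arrangement(pop: Population, region: tuple[int, int]
                              ) -> tuple[float, float]:
    """Mean number of deleterious mutations per haplotype within ``region``,
    separately for A and B haplotypes (NaN for an absent arrangement)."""
    lo, hi = region
    cat = pop.catalog
    counts = {ARR_A: [], ARR_B: []}
    for hap in pop.haplotypes():
        m = hap.muts
        if m.size:
            sel = (cat.pos[m] >= lo) & (cat.pos[m] < hi) & (cat.s[m] < 0)
            counts[hap.arrangement].append(int(sel.sum()))
        else:
            counts[hap.arrangement].append(0)
    mean_A = float(np.mean(counts[ARR_A])) if counts[ARR_A] else math.nan
    mean_B = float(np.mean(counts[ARR_B])) if counts[ARR_B] else math.nan
    return mean_A, mean_B


def bin_invasion_by_aod_symmetry(records: pd.DataFrame,
                                 d_aod: float = 0.005,
                                 d_sym: float = 0.0075,
                                 min_n: int = 20) -> pd.DataFrame:
    """Tile the (initial AOD, symmetry) plane and compute per-tile invasion
    probability.

    ``records`` needs columns ``aod``, ``symmetry``, ``invaded``.  Tiles have
    half-widths ``d_aod`` and ``d_sym``; tiles with at most ``min_n``
    observations are suppressed.
    """
    df = records.dropna(subset=["aod", "symmetry"]).copy()
    df["aod_bin"] = np.floor(df["aod"] / (2 * d_aod)).astype(int)
    df["sym_bin"] = np.floor(df["symmetry"] / (2 * d_sym)).astype(int)
    g = df.groupby(["aod_bin", "sym_bin"], as_index=False).agg(
        n=("invaded", "size"), invasion_prob=("invaded", "mean"))
    g["aod_center"] = (g["aod_bin"] + 0.5) * 2 * d_aod
    g["sym_center"] = (g["sym_bin"] + 0.5) * 2 * d_sym
    return g[g["n"] > min_n].reset_index(drop=True)
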
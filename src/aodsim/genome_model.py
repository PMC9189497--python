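"""Genome coordinate system, parameter containers and mutation-effect distributions.

The simulated genome consists of two chromosomes of equal length laid out on a
single linear 0-based, half-open coordinate axis (chromosome 2 is offset by the
length of chromosome 1).  A chromosomal inversion occupies a fixed interval on
chromosome 1 covering half of that chromosome (one quarter of the genome).
Selected mutations arise only inside a small set of uniformly spaced "allelic
content" segments; recombination operates over the whole genome.

Deleterious effects follow a gamma distribution of |s| (shape ``alpha_gamma``,
rate ``beta_gamma``); beneficial effects follow an exponential distribution of
|s| with mean ``kappa_exp``.  All coefficients are homozygous effects under a
multiplicative fitness scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "GenomeMap",
    "Mutation",
    "ORIGIN_P1",
    "ORIGIN_P2",
    "ORIGIN_POST",
    "build_genome_map",
    "sample_deleterious_effect",
    "sample_beneficial_effect",
    "sample_gc_tract_length",
    "rescale_config",
    "sampling_grid",
    "outcome_checkpoints",
    "load_config",
    "save_config",
]

# Origin codes for mutations.
ORIGIN_P1 = 0
ORIGIN_P2 = 1
ORIGIN_POST = 2

#: Generations at which time series are recorded (pre-rescaling scale).
BASE_SAMPLING_GRID = (
    10, 50, 100, 200, 500, 1000, 5000, 10_000, 25_000, 50_000,
    100_000, 125_000, 150_000, 200_000,
)

#: Generations at which the outcome of a still-polymorphic run is classified.
BASE_CHECKPOINTS = (100_000, 150_000, 200_000)


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of the simulation.

    Defaults are the study's headline parameter set (Drosophila-informed
    rates): per-bp deleterious mutation rate ``mu``, total recombination split
    into crossover ``rho`` and gene-conversion initiation ``gamma_gc``, a 20 Mb
    two-chromosome genome with 200 kb of allelic content in 5 kb segments, and
    gamma-distributed deleterious effects with fixed dominance ``h_del``.
    """

    mu: float = 4.5e-9                 # deleterious rate, per bp per generation
    beneficial_mu: float = 4.5e-12     # beneficial rate (post-admixture only)
    L: int = 20_000_000                # genome length (bp), two equal chromosomes
    rho: float = 3.0e-8                # crossover rate, per bp per meiosis
    gamma_gc: float = 1.8e-8           # gene-conversion initiation rate, per bp per meiosis
    lambda_gc: float = 500.0           # mean GC tract length (bp)
    T_BI: int = 200_000                # burn-in generations (divergence time)
    h_del: float = 0.0                 # dominance of deleterious mutations
    h_ben: float = 0.5                 # dominance of beneficial mutations
    N_BI: int = 2500                   # pre-admixture population size per population
    N_post: int = 2500                 # post-admixture size of P1
    alpha_gamma: float = 0.5           # gamma DFE shape
    beta_gamma: float = 10.0           # gamma DFE rate (E|s| = alpha/beta)
    kappa_exp: float = 0.001           # mean |s| of beneficial mutations
    scale_Q: float = 1.0               # cumulative rescaling factor applied so far
    T_max: int = 200_000               # post-admixture generation cap
    viability_threshold: float = 0.01  # karyotype mean fitness below this is "lethal"
    n_segments: int = 40               # number of allelic-content segments
    segment_len: int = 5_000           # length of each segment (bp)
    compensate_segment_mu: bool = True # concentrate the genome-wide mutation input mu*L into the segments
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("mu", "beneficial_mu", "rho", "gamma_gc", "lambda_gc",
                     "kappa_exp", "alpha_gamma", "beta_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("L", "T_BI", "T_max", "N_BI", "N_post", "n_segments", "segment_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("h_del", "h_ben"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.scale_Q < 1:
            raise ValueError("scale_Q must be >= 1")
        if not 0.0 < self.viability_threshold < 1.0:
            raise ValueError("viability_threshold must lie in (0, 1)")
        if self.n_segments * self.segment_len > self.L:
            raise ValueError("allelic-content segments do not fit in the genome")

    # -- derived quantities ------------------------------------------------

    @property
    def segment_total(self) -> int:
        """Total length of the allelic-content segments (bp)."""
        return self.n_segments * self.segment_len

    @property
    def r_total(self) -> float:
        """Total per-bp recombination rate (crossover + gene conversion)."""
        return self.rho + self.gamma_gc

    def gamete_del_rate(self) -> float:
        """Expected deleterious mutations per gamete per generation."""
        if self.compensate_segment_mu:
            return self.mu * self.L
        return self.mu * self.segment_total

    def gamete_ben_rate(self) -> float:
        """Expected beneficial mutations per gamete per generation."""
        if self.compensate_segment_mu:
            return self.beneficial_mu * self.L
        return self.beneficial_mu * self.segment_total


@dataclass(frozen=True)
class GenomeMap:
    """Physical layout: chromosome bounds, mutable segments, inversion interval.

    All intervals are 0-based half-open bp intervals on the linear genome.
    """

    chrom_bounds: tuple[tuple[int, int], tuple[int, int]]
    segments: tuple[tuple[int, int], ...]
    inversion: tuple[int, int]

    @property
    def L(self) -> int:
        return self.chrom_bounds[-1][1]

    @property
    def inversion_len(self) -> int:
        return self.inversion[1] - self.inversion[0]

    @property
    def chr_boundary(self) -> int:
        """Position separating the two freely assorting chromosomes."""
        return self.chrom_bounds[0][1]

    def segment_starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.segments], dtype=np.int64)

    def in_inversion(self, pos: np.ndarray | int) -> np.ndarray | bool:
        lo, hi = self.inversion
        return (np.asarray(pos) >= lo) & (np.asarray(pos) < hi)


@dataclass(frozen=True)
class Mutation:
    """A selected variant.  ``s`` is the signed homozygous effect."""

    id: int
    pos: int
    s: float
    h: float
    origin_pop: int  # ORIGIN_P1 | ORIGIN_P2 | ORIGIN_POST
    origin_gen: int

    def __post_init__(self) -> None:
        if self.s == 0.0:
            raise ValueError("selection coefficient must be non-zero")


def build_genome_map(config: SimulationConfig) -> GenomeMap:
    """Deterministic genome layout for a configuration.

    Segments of ``segment_len`` bp are uniformly spaced over ``[0, L)`` (the
    i-th segment starts at ``round(i * L / n_segments)``); the inversion is the
    centred half of chromosome 1.
    """
    L = config.L
    half = L // 2
    n = config.n_segments
    starts = np.round(np.arange(n) * (L / n)).astype(np.int64)
    segments = tuple((int(s), int(s) + config.segment_len) for s in starts)
    for (a0, a1), (b0, b1) in zip(segments, segments[1:]):
        if a1 > b0:
            raise ValueError("allelic-content segments overlap; reduce segment_len or n_segments")
    if segments[-1][1] > L:
        raise ValueError("allelic-content segments extend past the genome")
    inv_len = half // 2
    inv_start = (half - inv_len) // 2
    return GenomeMap(
        chrom_bounds=((0, half), (half, L)),
        segments=segments,
        inversion=(inv_start, inv_start + inv_len),
    )


def sample_deleterious_effect(rng: np.random.Generator,
                              config: SimulationConfig,
                              size: int | None = None):
    """Signed deleterious effect(s): s < 0 with |s| ~ Gamma(alpha, rate beta)."""
    scale = 1.0 / config.beta_gamma
    return -rng.gamma(config.alpha_gamma, scale, size=size)


def sample_beneficial_effect(rng: np.random.Generator,
                             config: SimulationConfig,
                             size: int | None = None):
    """Signed beneficial effect(s): s > 0 with |s| ~ Exponential(mean kappa)."""
    return rng.exponential(config.kappa_exp, size=size)


def sample_gc_tract_length(rng: np.random.Generator, lambda_gc: float,
                           size: int | None = None):
    """Gene-conversion tract length(s) in bp: Poisson with mean ``lambda_gc``."""
    if lambda_gc < 0:
        raise ValueError("lambda_gc must be >= 0")
    return rng.poisson(lambda_gc, size=size)


def _div_int(value: int, Q: float, name: str) -> int:
    scaled = value / Q
    out = int(round(scaled))
    if abs(scaled - out) > 1e-9:
        raise ValueError(f"{name}={value} is not divisible by Q={Q}")
    return out


def rescale_config(config: SimulationConfig, Q: float,
                   scale_selection: bool = True) -> SimulationConfig:
    """Diffusion rescaling by a factor ``Q``.

    Population sizes and generation counts shrink by ``Q``; mutation and
    recombination rates grow by ``Q``; with ``scale_selection`` (default) the
    selection-coefficient scale also grows by ``Q`` (gamma rate divided,
    exponential mean multiplied), so that N*mu*L, N*r*L and N*E[s] are
    preserved.  ``scale_selection=False`` leaves the fitness-effect
    distributions untouched (time-and-rate-only acceleration).
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if Q == 1:
        return config
    N_BI = _div_int(config.N_BI, Q, "N_BI")
    N_post = _div_int(config.N_post, Q, "N_post")
    if N_BI < 2 or N_post < 2:
        raise ValueError("rescaled population size smaller than 2")
    kwargs = dict(
        mu=config.mu * Q,
        beneficial_mu=config.beneficial_mu * Q,
        rho=config.rho * Q,
        gamma_gc=config.gamma_gc * Q,
        T_BI=max(1, _div_int(config.T_BI, Q, "T_BI")),
        T_max=max(1, _div_int(config.T_max, Q, "T_max")),
        N_BI=N_BI,
        N_post=N_post,
        scale_Q=config.scale_Q * Q,
    )
    if scale_selection:
        kwargs["beta_gamma"] = config.beta_gamma / Q
        kwargs["kappa_exp"] = config.kappa_exp * Q
    return replace(config, **kwargs)


def sampling_grid(config: SimulationConfig) -> tuple[int, ...]:
    """Time-series recording generations, rescaled by the cumulative factor."""
    Q = config.scale_Q
    gens = sorted({max(1, int(round(g / Q))) for g in BASE_SAMPLING_GRID})
    return tuple(g for g in gens if g <= config.T_max)


def outcome_checkpoints(config: SimulationConfig) -> tuple[int, ...]:
    """Outcome-classification generations, rescaled by the cumulative factor."""
    Q = config.scale_Q
    gens = sorted({max(1, int(round(g / Q))) for g in BASE_CHECKPOINTS})
    return tuple(g for g in gens if g <= config.T_max)


# -- config file I/O -------------------------------------------------------

def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as JSON (field names mirror SimulationConfig)."""
    Path(path).write_text(json.dumps(asdict(config), indent=2) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    """Read a configuration from JSON or TOML; unknown keys are rejected."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)
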
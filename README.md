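# aodsim

Forward-time Wright–Fisher simulation of supergene evolution after
introgression, and the statistics to analyse it.

## The problem

Supergenes — sets of tightly linked loci held together by suppressed
recombination between chromosomal arrangements — are spectacular cases of
long-term balanced polymorphism, but suppressed recombination also makes
them degenerate by accumulating recessive deleterious mutations. `aodsim`
simulates one origin scenario: two populations diverge in isolation, each
fixed for one arrangement of a chromosomal inversion (standard *B* in P1,
inverted *A* in P2); a single migrant then introduces the inverted
arrangement into P1. Because each population has fixed its own private
recessive deleterious mutations, the heterokaryotype (*AB*) masks both loads
and enjoys **associative overdominance (AOD)**,

```
s1' = 1 − W̄_AA / W̄_AB      s2' = 1 − W̄_BB / W̄_AB      s' = min(s1', s2')
```

which can carry the new arrangement to intermediate frequency. Further
mutation accumulation then decides between loss of the polymorphism, a
**half-lethal** system (one homokaryotype inviable), or the curious
**balanced lethal** state in which both homokaryotypes are inviable, only
heterokaryotypes reproduce, and half of all zygotes die every generation.

The package is aimed at population geneticists who want a hackable,
pure-Python model of this process: per-mutation bookkeeping (gamma DFE,
dominance, multiplicative fitness), inversion-aware meiosis (crossovers
suppressed in heterokaryotypes inside the inversion; gene conversion with
Poisson tract lengths as the only gene flux there), explicit drift/mutational
load decomposition, and an experiment layer for factorial designs with
reproducible seeding.

## A worked example

```python
import numpy as np
from aodsim.burnin import run_burnin
from aodsim.experiment import desk_scale_config
from aodsim.introgression import run_replicate

cfg = desk_scale_config()            # N_BI=25, T_BI=2000: the 100x-reduced
state = run_burnin(cfg, np.random.default_rng(1))   # analogue of N=2500/200k

L = state.summary["loads"]["P1"]
print(L.drift_load, L.mutational_load, L.drift_fraction)
# 0.299 0.000 1.00   -- the supergene region's load is (almost) entirely
#                       private fixed mutations: drift load

res = run_replicate(state, rng=np.random.default_rng(7))
print(res.status, res.invasion)
# POLYMORPHIC_AT_TMAX True  -- the migrant arrangement invaded and the
#                              polymorphism held to the generation cap
row = res.timeseries[0]
print(round(row["sp"], 2), round(row["freq_A"], 3))
# 0.73 0.04  -- strong AOD right after admixture, at migrant frequency 1/N
```

`res.timeseries` carries, on a fixed sampling grid, inversion frequency,
karyotype mean fitnesses, AOD and its symmetry, mean fitness, and per-
arrangement mutation counts; `res.outcome_at` classifies still-polymorphic
populations at the late checkpoints as `POLY_BOTH_VIABLE`, `HALF_LETHAL` or
`BALANCED_LETHAL` (threshold: karyotype mean fitness 0.01).

The `examples/` scripts walk through each capability: burn-in divergence and
load decomposition, a single followed replicate, and the balanced-lethal
fixture with its Mendelian 50% zygote loss. A thin CLI (`aodsim burnin`,
`aodsim run`, `aodsim block`, `aodsim fixtures`) wraps the same functions
for shell use.

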
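"""One introgression replicate, followed through time.

A single migrant homozygous for the inverted arrangement enters the
bottlenecked focal population; the time series shows inversion frequency,
karyotype mean fitnesses and associative overdominance (s') on the standard
sampling grid.
"""

import numpy as np

from aodsim.burnin import run_burnin
from aodsim.experiment import desk_scale_config
from aodsim.introgression import run_replicate

cfg = desk_scale_config()
state = run_burnin(cfg, np.random.default_rng(1))

res = run_replicate(state, rng=np.random.default_rng(7))
print(f"status: {res.status} at generation {res.end_generation}; "
      f"invaded: {res.invasion}")
df = res.timeseries_frame()
if not df.empty:
    cols = ["generation", "freq_A", "W_AA", "W_AB", "W_BB", "sp", "symmetry",
            "mean_fitness"]
    print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print()
    print("sp is the AOD statistic s' = min(1 - W_AA/W_AB, 1 - W_BB/W_AB):")
    print("positive values mean the heterokaryotype is fitter than both")
    print("homokaryotypes, i.e. balancing selection on the inversion.")
for gen, outcome in res.outcome_at.items():
    print(f"outcome at generation {gen}: {outcome}")
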
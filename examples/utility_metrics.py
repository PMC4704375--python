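"""How much analytic value survives the masking, as a function of d and k.

Measures, on a 100-point synthetic file, the fraction of records keeping
their exact nearest neighbour under the released matrix, and the Spearman
rank correlation of distances to a central and a border anchor record.
"""

import numpy as np

from lipmask import default_region, utility_sweep
from lipmask.geometry import sample_uniform_latlon

region = default_region()
points = sample_uniform_latlon(region, 100, np.random.default_rng(5))

df = utility_sweep(points, region, dims=[5, 20], sizes=[5, 20, 50], replicates=5, seed=9)
summary = df.groupby(["d", "k"])[["nn_rate", "rho_central", "rho_border"]].mean().round(3)
print(summary)
# nn_rate near 1 means clustering-style analyses are barely affected;
# it degrades as k grows (heavier contraction) and recovers as d grows.
# Rank correlations to the central anchor exceed those to the border
# anchor because long distances are contracted more than short ones.
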
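"""Latin-hypercube sampling of the uncertain bone/implant stiffnesses.

Young's moduli are normally distributed (cortical bone 17000 +/- 3400 MPa,
cancellous 100 +/- 20, titanium 110000 +/- 4400, PMMA 3000 +/- 300);
LHS stratification places exactly one draw in each equal-probability
stratum of every marginal, which stabilizes small-sample estimates.
"""

import numpy as np
from scipy import stats

from fusegap import lhs_sample, material_table

dists = material_table("real")
print("phase distributions (E mean (SD) [MPa], poisson):")
for d in dists:
    print(f"  {d.name:10s} {d.E_mean:9.0f} ({d.E_sd:.0f})   nu={d.poisson}")

samples = lhs_sample(dists, n=40, seed=42)
E_cort = np.array([s.E["cortical"] for s in samples])
print(f"\n40 LHS draws of cortical E: mean {E_cort.mean():.0f} MPa, "
      f"SD {E_cort.std(ddof=1):.0f} MPa")

# verify the stratification: one draw per CDF stratum
u = stats.norm.cdf(E_cort, loc=17000, scale=3400)
occupancy = np.bincount((u * 40).astype(int), minlength=40)
print(f"stratum occupancy (should be all ones): "
      f"min {occupancy.min()}, max {occupancy.max()}")
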
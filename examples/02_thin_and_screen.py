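"""Clean occurrence records and screen predictors for collinearity.

Spatial thinning enforces a 5-km minimum distance between records
(reducing sampling autocorrelation); stepwise VIF drops predictors that
are linear combinations of the others.
"""

import numpy as np
import pandas as pd

import sdmniche as sn
from sdmniche.occurrences import OccurrenceSet, pairwise_distance_km

# a clustered set of survey coordinates (lon/lat, degrees)
rng = np.random.default_rng(0)
pts = np.vstack([
    np.column_stack([46.0 + rng.random(60) * 0.2, 34.0 + rng.random(60) * 0.2]),
    np.column_stack([47.5 + rng.random(40) * 1.0, 35.0 + rng.random(40) * 1.0]),
])
occ = OccurrenceSet(pts, species_label="demo", crs_kind="geographic-degrees")
thinned = sn.spatial_thin(occ, min_dist=5.0, rng_seed=1, n_repeats=50)
d = pairwise_distance_km(thinned)
print(f"thinning: {len(occ)} -> {len(thinned)} records; "
      f"closest remaining pair {d[np.triu_indices(len(thinned), 1)].min():.2f} km")

# predictor table where x3 is (almost) the sum of x1 and x2
x1, x2 = rng.standard_normal((2, 400))
table = pd.DataFrame({"x1": x1, "x2": x2,
                      "x3": x1 + x2 + 0.05 * rng.standard_normal(400),
                      "x4": rng.standard_normal(400)})
report = sn.vif_stepwise(table, threshold=10.0)
print(f"VIF screening removed {report.removed}, retained {report.retained}")
print("final VIFs:", {k: round(v, 2) for k, v in report.vif.items()})
# x3 duplicates the information in x1+x2, so its variance inflation
# explodes and stepwise screening deletes it first.
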
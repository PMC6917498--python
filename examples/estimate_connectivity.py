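"""Ridge partial correlations for one subject's component time series.

Shows the estimator at the analysis default (rho=1 on the diagonal-normalized
covariance) against the nearly-unregularized estimate, and the canonical
Fisher-z edge vector used by all group analyses.
"""

import numpy as np

from geoconn import (
    CohortConfig,
    ConnectivityConfig,
    extract_edges,
    generate_cohort,
    ridge_partial_correlation,
)

cfg = CohortConfig(
    group_sizes={"TD": 1},
    component_labels=("DMN", "OTC", "PVC", "DAN"),
    seed=4,
)
_, timeseries, _ = generate_cohort(cfg)
ts = timeseries[0]

r_ridge = ridge_partial_correlation(ts, ConnectivityConfig(rho=1.0))
r_raw = ridge_partial_correlation(
    ts, ConnectivityConfig(rho=1e-8, normalize_covariance=False)
)

np.set_printoptions(precision=3, suppress=True)
print("components:", list(ts.component_labels))
print("partial correlations, rho=1 (analysis default):")
print(r_ridge)
print("partial correlations, rho ~ 0 (unregularized):")
print(r_raw)

edges = extract_edges(r_ridge, ts.subject_id, ts.component_labels, fisher=True)
print("Fisher-z edge vector (canonical lower-triangle order):")
for (ci, cj), v in zip(edges.labels, edges.values):
    print(f"  {ci}-{cj}: {v:+.3f}")
print("ridge shrinks every edge toward zero (stabilizing the estimate at "
      "T=150); the DMN-OTC edge reflects the planted TD coupling of 0.30.")
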
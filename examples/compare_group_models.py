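"""Case-control vs subtype vs transdiagnostic models of one edge.

A cohort is generated with a GeoPref-specific DMN-OTC deficit; the three
competing designs are then fit on the identical eye-tracked subject set and
compared by AIC (with support bands) and 5-fold cross-validated MAPE.
"""

import pandas as pd

from geoconn import CohortConfig, EdgeEffect, compare_models, compute_edge_vectors, generate_cohort

cfg = CohortConfig(
    component_labels=("DMN", "OTC", "PVC", "DAN"),
    edge_effects=[
        EdgeEffect(("DMN", "OTC"), grp, 0.30)
        for grp in ["TD", "TD ASDSib", "LD/DD", "nonGeo ASD", "ASD-noET"]
    ]
    + [EdgeEffect(("DMN", "OTC"), "GeoPref ASD", 0.00)],
    behavior_coupling=[],
    seed=17,
)
records, timeseries, _ = generate_cohort(cfg)
edge_vectors = compute_edge_vectors(timeseries)

idx = edge_vectors[0].labels.index(("OTC", "DMN"))
series = pd.Series({ev.subject_id: ev.values[idx] for ev in edge_vectors})
report = compare_models(series, records, k=5, seed=0)

print(f"DMN-OTC edge, n = {report.n_subjects} subjects with eye tracking")
print(f"{'scheme':18s} {'AIC':>9s} {'dAIC':>6s} {'support':>26s} {'MAPE':>8s}")
for scheme, fit in report.fits.items():
    print(
        f"{scheme:18s} {fit.aic:9.2f} {fit.delta_aic:6.2f} "
        f"{fit.support:>26s} {fit.mape_mean:8.1f}"
    )
print(f"preferred by AIC:  {report.preferred_by_aic}")
print(f"preferred by MAPE: {report.preferred_by_mape}")
print(
    "the subtype model should win here: splitting ASD by the 69% fixation "
    "cutoff captures the planted GeoPref-specific deficit that the pooled "
    "case-control ASD label averages away."
)
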
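"""Kaplan-Meier medians, log-rank test and a univariate Cox forest table.

Simulates a cohort whose latent benefit drives both the biomarkers and
progression-free survival, then evaluates PFS across the biomarker groups
the pipeline derives.
"""

import numpy as np

from dynamark.io import build_ctdna_statuses, build_scan_pairs
from dynamark.pet import classify_consist
from dynamark.simulate import CohortConfig, simulate_cohort
from dynamark.survival import forest_univariate, km_median, logrank

cohort = simulate_cohort(CohortConfig(n_patients=400, seed=33))
pairs = build_scan_pairs(cohort.lesions, cohort.scans)
resp15 = {p.patient_id: classify_consist(p, cutoff_pct=15).responder for p in pairs}
detected = {
    s.patient_id: s.detected_d14
    for s in build_ctdna_statuses(cohort.variants, cohort.samples)
}

clin = cohort.clinical.copy()
clin["consist_15"] = clin["patient_id"].map(resp15).astype(float)
clin["ctdna_d14"] = clin["patient_id"].map(
    lambda p: np.nan if detected.get(p) is None else float(detected[p])
)
clin["age_le_60"] = (clin["age_years"] <= 60).astype(int)

for label, mask in [("responder", clin["consist_15"] == 1), ("non-responder", clin["consist_15"] == 0)]:
    med = km_median(clin.loc[mask, "pfs_months"], clin.loc[mask, "event"])
    print(f"median PFS, PET {label}s: {med:.1f} months (n={mask.sum()})")
stat, p = logrank(clin["pfs_months"], clin["event"], clin["consist_15"])
print(f"log-rank responders vs non-responders: chi2={stat:.2f}, p={p:.4f}")

table = forest_univariate(
    clin, ["consist_15", "ctdna_d14", "age_le_60", "visceral", "prior_cdk46"]
)
print("\nunivariate Cox hazard ratios (HR < 1 = longer PFS):")
print(table.round(3).to_string(index=False))

# The metabolic responders live longer and the responder HR sits well below
# one; purely prognostic noise covariates hover around HR 1 with wide CIs.
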
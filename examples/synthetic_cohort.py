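"""Generate a ground-truth cohort and check the pipeline recovers its parameters.

Draws a cohort whose latent benefit status drives lesion SUV decreases,
ctDNA clearance and exponential PFS, writes the five exchange tables, then
runs the full pipeline back over them and compares estimates to truth.
"""

from dynamark.simulate import CohortConfig, recover_parameters, simulate_cohort

cfg = CohortConfig(n_patients=800, seed=14, p_latent_benefit=0.5)
cohort = simulate_cohort(cfg)
print(
    f"simulated {cfg.n_patients} patients: {len(cohort.lesions)} lesion rows, "
    f"{len(cohort.variants)} variant rows, {len(cohort.clinical)} clinical rows"
)
cohort.write("scratch/example_cohort")  # lesions/scans/variants/clinical/samples/truth .tsv

report = recover_parameters(cohort)
print(f"generating HR (benefit vs not): {report.generating_hr:.3f}")
print(f"  Cox estimate on latent benefit: {report.hr_latent_benefit:.3f}")
print(f"  Cox estimate on the Consist-15% readout: {report.hr_consist15:.3f}")
print(
    f"KM medians benefit / non-benefit: {report.km_median_benefit:.1f} / "
    f"{report.km_median_nonbenefit:.1f} months (generated 6.4 / 2.2)"
)
print(
    f"baseline ctDNA detection: {report.detection_rate_baseline_pct:.1f}% "
    f"(configured {report.configured_detection_baseline_pct:.1f}%)"
)
print(f"median CDR among evaluable patients: {report.median_cdr:.3f}")

# The latent-benefit Cox estimate brackets the generating hazard ratio; the
# imaging-readout estimate is attenuated toward 1 because the classifier is
# a noisy surrogate of benefit — exactly the behaviour expected of an early
# response biomarker.
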
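"""Follow a patient's plasma ctDNA from baseline through day 14.

Filters raw variant calls, makes the detection calls, and computes the
circulating DNA ratio (CDR: total mutated copies/ml at day 14 over
baseline) plus the VAF stratum and baseline-normalised trajectory.
"""

from dynamark import (
    VariantCall,
    compute_cdr,
    filter_variants,
    normalize_to_baseline,
    patient_status,
    vaf_stratum,
)


def call(tp, gene, prot, cons, vaf, mut, cov=8000, fwd=0.5):
    return VariantCall(
        patient_id="patient-01",
        timepoint=tp,
        gene=gene,
        protein_change=prot,
        consequence=cons,
        classification="pathogenic",
        vaf_pct=vaf,
        mut_copies_per_ml=mut,
        total_copies_per_ml=mut * 100 / max(vaf, 0.01),
        coverage=cov,
        fwd_fraction=fwd,
    )


raw = [
    call("baseline", "PIK3CA", "p.H1047R", "missense", vaf=11.0, mut=64.0),
    call("baseline", "ESR1", "p.D538G", "missense", vaf=4.0, mut=21.0),
    call("baseline", "TP53", "p.R175H", "missense", vaf=2.0, mut=9.0, cov=80),  # shallow
    call("baseline", "PTEN", "p.T319T", "silent", vaf=1.0, mut=4.0),            # silent
    call("d14", "PIK3CA", "p.H1047R", "missense", vaf=1.1, mut=5.1),
]

retained = filter_variants(raw)
print(f"retained {len(retained)} of {len(raw)} calls "
      f"(dropped: shallow coverage, silent change)")

status = patient_status("patient-01", retained)
print(f"detected baseline: {status.detected_baseline}, day 14: {status.detected_d14}")
print(f"CDR = {status.cdr:.3f} "
      "(day-14 mutated copies/ml over baseline, summed across mutations)")
print(f"max VAF baseline {status.max_vaf_baseline}% -> stratum {vaf_stratum(status.max_vaf_baseline)}")

traj = normalize_to_baseline({"baseline": 64.0, "d14": 5.1})
print("PIK3CA copies normalised to baseline:", {k: round(v, 3) for k, v in traj.items()})

base = [c for c in retained if c.timepoint == "baseline"]
d14 = [c for c in retained if c.timepoint == "d14"]
assert status.cdr == compute_cdr(base, d14)

# A CDR of ~0.06 means the treatment cleared ~94% of circulating mutant
# copies in two weeks; the ESR1 clone fell below detection entirely and
# contributes zero to the numerator.
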
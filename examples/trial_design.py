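"""Size a two-arm log-rank comparison from fixed-horizon survival fractions.

Turns 6-month PFS of 37% (non-responders) versus 70% (responders) into the
exponential-survival hazard ratio and the Schoenfeld event requirement at
90% power, two-sided alpha 0.05, with 59% of patients expected in the
non-responder arm.
"""

from dynamark import DesignSpec, exponential_hr, schoenfeld_events

hr = exponential_hr(s_control=0.37, s_experimental=0.70)
print(f"hazard ratio under exponential survival: {hr:.4f} (~{hr:.2f})")

events = schoenfeld_events(hr=0.36, alpha_two_sided=0.05, power=0.90, allocation_fraction=0.59)
print(f"required PFS events (alpha 0.05 two-sided, power 0.90, allocation 0.59): {events}")

balanced = schoenfeld_events(hr=0.36, allocation_fraction=0.5)
print(f"same design with balanced arms: {balanced} events")

spec = DesignSpec(s_control=0.37, s_experimental=0.70, allocation_fraction=0.59)
assert spec.required_events() == events

# 42 events suffice at the observed 59/41 split; a balanced trial would need
# slightly fewer because p(1-p) peaks at 0.5.
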
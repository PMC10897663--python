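"""Stent-graft oversizing arithmetic and the eligibility window.

A 26 mm device must be oversized 10-20% relative to the proximal landing
zone: the admissible aortic diameters invert to 21.7-23.6 mm, and the
cohort-mean 22.8 mm landing zone gives 14% oversizing.
"""

from archpwv import (eligibility_range, filter_eligible, generate_cohort,
                     oversizing_fraction)

d_graft = 26.0
lo, hi = eligibility_range(d_graft, 0.10, 0.20)
print(f"eligibility window for a {d_graft:.0f} mm graft: {lo}-{hi} mm")

ov = 100.0 * oversizing_fraction(d_graft, 22.8)
print(f"oversizing in a 22.8 mm landing zone: {ov:.0f}%")

cohort = generate_cohort(24, seed=4)
eligible = filter_eligible(cohort, d_graft, 0.10, 0.20)
print(f"simulated cohort: {len(eligible)}/24 specimens eligible "
      f"({100 * len(eligible) / 24:.0f}%)")
# Roughly half of a simulated cohort with the observed diameter spread
# falls inside the 10-20% oversizing window.
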
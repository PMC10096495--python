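"""Re-analyse simulated SMART-style surveys into CDR / U5DR estimates.

Each survey's intercept-only Poisson fit gives the rate as total deaths over
total person-time, with a CR0 cluster-robust 95% interval; the eligibility
filter mirrors the exclusion rules used for real survey collections.
"""

import crisismort as cm

world = cm.generate_world(cm.WorldConfig(seed=1))
surveys = cm.generate_surveys(world, 8, seed=2)

eligible, excl = cm.filter_eligible([s.meta for s in surveys])
print(f"{len(eligible)} of {len(surveys)} surveys eligible for modelling")

print(f"{'survey':>8} {'district':>9} {'CDR':>6} {'95% CI':>14} {'U5DR':>6}")
for sv in surveys:
    cdr, u5 = cm.estimate_rates(sv)
    print(f"{sv.meta.survey_id:>8} {sv.meta.district:>9} {cdr.rate:6.2f} "
          f"[{cdr.ci_low:5.2f},{cdr.ci_high:5.2f}] {u5.rate:6.2f}")
print("\nrates are deaths per 10,000 person-days (child-days for U5DR); a CDR above")
print("1.0 is the conventional emergency threshold, so values around 0.4-0.8 describe")
print("a strained but not catastrophic situation.")
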
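"""Clinical response definitions on the 14-patient reference cohort.

Applies the 50% HDRS-17 rule and the 3-consecutive-week stability
criterion, and prints the cohort summary table values.
"""

import scclfp as s

outcomes = s.load_reference_cohort()
summary = s.cohort_summary(outcomes)

print(f"patients: {summary['n_patients']}, "
      f"6-month responders: {summary['n_responders']}")
r = summary["rounded"]
print(f"baseline HDRS-17: {r['baseline_mean']} ({r['baseline_sd']})")
print(f"6-month HDRS-17:  {r['month6_mean']} ({r['month6_sd']})")
ttr = summary["time_to_stable_weeks"]
print(f"time to stable response: {ttr['mean']:.1f} ({ttr['sd']:.0f}) weeks "
      f"over {ttr['n']} patients (one never reached a stable response)")

demo = s.time_to_stable_response({1: 20, 2: 18, 3: 9, 4: 8, 5: 9, 6: 9}, baseline=20)
print(f"weekly series demo: stable response from week {demo}")
# Response = >=50% decrease from baseline (boundary counts); stability =
# the first week starting 3 consecutive responding weeks.
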
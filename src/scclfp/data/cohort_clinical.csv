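patient_id,baseline_hdrs17,month6_hdrs17,weekly_hdrs17,time_to_stable_weeks
1,25.5,12,,26
2,24.25,13,,40
3,27.5,6,,8
4,23.75,9,,25
5,22,6,,24
6,22.75,16,,
7,20.25,17,,74
8,26.25,12,,22
9,20,7,,4
10,25.25,6,,5
11,21,6,,4
12,21.5,9,,4
13,29.25,3,,3
14,23.25,8,,19
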
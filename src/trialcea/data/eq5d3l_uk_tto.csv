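# EQ-5D-3L UK TTO value set (MVH study), additive-decrement form.
# source: Dolan P. Modeling valuations for EuroQol health states.
#         Medical Care 1997;35(11):1095-1108 (UK general-population TTO tariff)
# transcribed: 2026-09-26
# form: utility = 1 - constant(if any dysfunction) - sum(dimension decrements)
#       - n3(if any dimension at level 3); range -0.594 (33333) to 1.000 (11111)
# md5: 8d0752a90f7b9dd708fabab531218476
term,dimension,level,decrement
constant,any,,0.081
n3,any,3,0.269
decrement,mobility,2,0.069
decrement,mobility,3,0.314
decrement,self_care,2,0.104
decrement,self_care,3,0.214
decrement,usual_activities,2,0.036
decrement,usual_activities,3,0.094
decrement,pain_discomfort,2,0.123
decrement,pain_discomfort,3,0.386
decrement,anxiety_depression,2,0.071
decrement,anxiety_depression,3,0.236
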
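term,dimension,level,value
any_problem,,,0.10
any_level3,,,0.05
decrement,mobility,2,0.06
decrement,mobility,3,0.28
decrement,self_care,2,0.08
decrement,self_care,3,0.20
decrement,usual_activities,2,0.03
decrement,usual_activities,3,0.09
decrement,pain_discomfort,2,0.10
decrement,pain_discomfort,3,0.254
decrement,anxiety_depression,2,0.05
decrement,anxiety_depression,3,0.10
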
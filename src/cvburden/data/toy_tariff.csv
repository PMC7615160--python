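dimension,level,decrement
mobility,1,0.0
mobility,2,0.04
mobility,3,0.08
mobility,4,0.16
mobility,5,0.30
self_care,1,0.0
self_care,2,0.03
self_care,3,0.06
self_care,4,0.12
self_care,5,0.22
usual_activities,1,0.0
usual_activities,2,0.03
usual_activities,3,0.07
usual_activities,4,0.13
usual_activities,5,0.24
pain_discomfort,1,0.0
pain_discomfort,2,0.05
pain_discomfort,3,0.10
pain_discomfort,4,0.19
pain_discomfort,5,0.32
anxiety_depression,1,0.0
anxiety_depression,2,0.04
anxiety_depression,3,0.08
anxiety_depression,4,0.15
anxiety_depression,5,0.26
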
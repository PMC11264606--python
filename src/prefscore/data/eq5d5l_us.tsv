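# instrument: EQ-5D-5L
# kind: additive
# version: US tariff (TTO valuation)
# anchor: 1.0
# minimum: -0.573
# maximum: 1.0
item	level	decrement
mobility	1	0.0
mobility	2	0.096
mobility	3	0.122
mobility	4	0.237
mobility	5	0.322
self_care	1	0.0
self_care	2	0.089
self_care	3	0.107
self_care	4	0.220
self_care	5	0.261
usual_activities	1	0.0
usual_activities	2	0.068
usual_activities	3	0.101
usual_activities	4	0.255
usual_activities	5	0.255
pain_discomfort	1	0.0
pain_discomfort	2	0.060
pain_discomfort	3	0.098
pain_discomfort	4	0.318
pain_discomfort	5	0.414
anxiety_depression	1	0.0
anxiety_depression	2	0.057
anxiety_depression	3	0.123
anxiety_depression	4	0.299
anxiety_depression	5	0.321
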
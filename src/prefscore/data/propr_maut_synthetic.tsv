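# instrument: PROPr
# kind: maut
# version: synthetic stand-in calibrated to the published anchors (-0.022, 0.954)
# minimum: -0.022
# maximum: 0.954
# weight.physical_function: 0.405
# weight.pain_interference: 0.384
# weight.depression: 0.247
# weight.fatigue: 0.283
# weight.social_roles: 0.264
# weight.sleep_disturbance: 0.210
# weight.cognitive_function: 0.199
domain	knot_score	disutility
physical_function	-3.0	1.0
physical_function	-2.0	0.75
physical_function	-1.0	0.45
physical_function	0.0	0.20
physical_function	1.0	0.08
physical_function	2.0	0.02
physical_function	3.0	0.0
pain_interference	-3.0	0.0
pain_interference	-2.0	0.02
pain_interference	-1.0	0.08
pain_interference	0.0	0.20
pain_interference	1.0	0.45
pain_interference	2.0	0.75
pain_interference	3.0	1.0
depression	-3.0	0.0
depression	-2.0	0.02
depression	-1.0	0.08
depression	0.0	0.20
depression	1.0	0.45
depression	2.0	0.75
depression	3.0	1.0
fatigue	-3.0	0.0
fatigue	-2.0	0.02
fatigue	-1.0	0.08
fatigue	0.0	0.20
fatigue	1.0	0.45
fatigue	2.0	0.75
fatigue	3.0	1.0
social_roles	-3.0	1.0
social_roles	-2.0	0.75
social_roles	-1.0	0.45
social_roles	0.0	0.20
social_roles	1.0	0.08
social_roles	2.0	0.02
social_roles	3.0	0.0
sleep_disturbance	-3.0	0.0
sleep_disturbance	-2.0	0.02
sleep_disturbance	-1.0	0.08
sleep_disturbance	0.0	0.20
sleep_disturbance	1.0	0.45
sleep_disturbance	2.0	0.75
sleep_disturbance	3.0	1.0
cognitive_function	-3.0	1.0
cognitive_function	-2.0	0.75
cognitive_function	-1.0	0.45
cognitive_function	0.0	0.20
cognitive_function	1.0	0.08
cognitive_function	2.0	0.02
cognitive_function	3.0	0.0
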
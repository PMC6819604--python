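sample_id	age	sex	true_group
wf1_1	0.3	F	1
wf1_2	0.3	M	1
wf1_3	0.3	F	1
wf2_1	1.0	F	2
wf2_2	1.0	M	2
wf2_3	1.0	F	2
wf3_1	2.0	F	3
wf3_2	2.0	M	3
wf3_3	2.0	F	3
wf4_1	5.0	F	4
wf4_2	5.0	M	4
wf4_3	5.0	F	4
wf5_1	15.0	F	5
wf5_2	15.0	M	5
wf5_3	15.0	F	5
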
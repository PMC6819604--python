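sample_id	inc	dec	bump	dip	bg1	bg2
wf1_1	100	500	100	500	400	800
wf1_2	200	1000	200	1000	800	1600
wf1_3	300	1500	300	1500	1200	2400
wf2_1	200	400	400	200	400	800
wf2_2	400	800	800	400	800	1600
wf2_3	600	1200	1200	600	1200	2400
wf3_1	300	300	500	100	400	800
wf3_2	600	600	1000	200	800	1600
wf3_3	900	900	1500	300	1200	2400
wf4_1	400	200	300	300	400	800
wf4_2	800	400	600	600	800	1600
wf4_3	1200	600	900	900	1200	2400
wf5_1	500	100	100	500	400	800
wf5_2	1000	200	200	1000	800	1600
wf5_3	1500	300	300	1500	1200	2400
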
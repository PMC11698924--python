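# graded-exercise constraint sets: fixed O2 uptake and ATP demand per %VO2max
# with literature carbohydrate (CHO) vs beta-oxidation share targets
percent_vo2max	o2_flux	atp_flux	cho_share	betaox_share
25	-3.7	14.6	0.4	0.6
65	-7.9	36.52	0.5	0.5
85	-11.1	54.8	0.8	0.2
100	-14.0	75.0	1.0	0.0
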
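# SYNTHETIC stand-in for transcriptome-derived calpainopathy regulations:
# 18 seeded expression fold-changes (source=rnaseq) on mini-muscle reactions,
# plus the two published glycolytic activity changes and one qualitative warning.
reaction_id	source	magnitude	citation_tag
TCA	rnaseq	2.4847645217113588	synthetic:20241209:0
TCA	rnaseq	0.4845458429648919	synthetic:20241209:1
BETA_OX	rnaseq	2.3892079466618927	synthetic:20241209:2
AA_DEG	rnaseq	0.4976544977342992	synthetic:20241209:3
BETA_OX	rnaseq	2.1047525520519175	synthetic:20241209:4
GLYCOLYSIS	rnaseq	0.9050866400143005	synthetic:20241209:5
ETC_NADH	rnaseq	1.4290535718672988	synthetic:20241209:6
ETC_NADH	rnaseq	0.4487878976014456	synthetic:20241209:7
BETA_OX	rnaseq	2.063447621317832	synthetic:20241209:8
ETC_NADH	rnaseq	0.34848836776835085	synthetic:20241209:9
BETA_OX	rnaseq	2.3481204221610974	synthetic:20241209:10
KETOLYSIS	rnaseq	0.7018110895066044	synthetic:20241209:11
GLYCOLYSIS	rnaseq	1.7758040539863233	synthetic:20241209:12
ETC_NADH	rnaseq	0.3561546600310632	synthetic:20241209:13
ETC_FADH2	rnaseq	1.3747332667150864	synthetic:20241209:14
PDH	rnaseq	0.4899161595145012	synthetic:20241209:15
TCA	rnaseq	2.0643714486636258	synthetic:20241209:16
AA_DEG	rnaseq	0.5369310801732441	synthetic:20241209:17
GLYCOLYSIS	activity	133.0	aldolase activity +133% vs control
LDH	activity	287.0	lactate dehydrogenase activity +287% vs control
TCA	qualitative_warning		citrate synthase: inconsistent reports; capped at control max
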
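gene	region	expression_group	depot	categories
SLC19A3	2q36.3	specific_all	both	Obesity
LVRN	5q23.1	specific_all	subcutaneous	Blood Lipids
LEP	7q32.1	specific_all	both	Type 2 diabetes
FABP4	8q21.13	specific_all	both	Obesity
ITLN1	1q23.3	specific_all	omental	Inflammation
ALOX15	17p13.2	specific_all	omental	Inflammation
PPARG	3p25.2	enhanced_except1	both	Blood Lipids;Inflammation;Obesity;Type 2 diabetes
CD36	7q21.11	enhanced_except1	both	Blood Lipids
CD300LG	17q21.31	enhanced_except1	both	Blood Lipids
IL6	7p15.3	enhanced_except1	omental	Inflammation
HAS1	19q13.41	enhanced_except1	omental	Blood Lipids
GPAM	10q25.2	enhanced_except2	both	Blood Lipids
ANGPTL4	19p13.2	enhanced_except2	subcutaneous	Blood Lipids
UPK3B	7q11.23	enhanced_except2	omental	Obesity
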
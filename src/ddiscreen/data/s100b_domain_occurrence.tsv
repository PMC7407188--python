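# Reference per-domain occurrence of S100B-interacting domains in the three virtual
# gut metaproteomes (healthy controls CT, Crohn disease CD, ulcerative colitis UC),
# with the published expected-by-chance values.
domain	obs_CT	exp_CT	obs_CD	exp_CD	obs_UC	exp_UC	description
PF00036	35	110	16	100	17	97	Helix-loop-helix motif of calcium-binding proteins
PF00069	35255	33790	16544	30657	13444	29731	Protein kinase domain
PF13895	149	76	12	69	10	67	Immunoglobulin domain
PF00612	8	20	9	18	9	17	IQ calmodulin-binding motif
PF00149	44022	43137	41838	39136	41095	37955	Calcineurin-like phosphoesterase
PF13202	1962	3421	2420	3104	2524	3010	EF hand
PF13499	2192	1226	696	1113	724	1079	EF-hand domain pair
PF13405	60	55	56	50	58	49	EF-hand domain
PF00063	2	3	2	3	2	3	Myosin head (motor domain)
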
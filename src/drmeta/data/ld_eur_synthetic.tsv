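SNP_A	SNP_B	DP	R2	POP
rs7903146	rs7074440	0.95	0.91	EUR
rs7903146	rs34872471	1.00	0.99	EUR
rs7903146	rs11196205	0.87	0.62	EUR
rs7903146	rs290487	0.41	0.05	EUR
rs4462262	rs900001	0.92	0.85	EUR
rs4462262	rs900002	0.85	0.55	EUR
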
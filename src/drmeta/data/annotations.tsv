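rsid	location_class	nearest_gene	sift	polyphen	cadd	regulomedb_rank	eqtl_gene	eqtl_p
rs4462262	intergenic	IPMK	na	na	7.10	5	na	na
rs7903146	intronic	TCF7L2	na	na	3.27	5	TCF7L2	2.9e-7
rs7074440	intronic	TCF7L2	na	na	10.10	2b	TCF7L2	2.1e-6
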
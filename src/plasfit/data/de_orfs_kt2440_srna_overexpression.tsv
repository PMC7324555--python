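orf_id	gene_name	cog_code	product	direction
PP_0042	PP_0042	–	Hypothetical protein	up
PP_0608	PP_0608	–	Hypothetical protein	up
PP_1185	oprH	M	Outer membrane protein H1	up
PP_1186	phoP	T	Two component transcriptional regulator	up
PP_1443	lon-1	O	ATP-dependent protease La	up
PP_1487	PP_1487	S	Hypothetical protein	up
PP_1982	ibpA	O	Heat shock protein Hsp20	up
PP_2197	PP_2197	–	Hypothetical protein	up
PP_2198	PP_2198	G	Glucose sorbosone dehydrogenase	up
PP_2285	PP_2285	–	Hypothetical protein	up
PP_2454	rbsB	G	Monosaccharide-transporting ATPase	up
PP_2520	PP_2520	–	Hypothetical protein	up
PP_2909	PP_2909	–	Hypothetical protein	up
PP_3172	PP_3172	L	Group II intron-encoding maturase	up
PP_3305	PP_3305	P	TerC family membrane protein	up
PP_3328	PP_3328	R	Ring-cleaving dioxygenase	up
PP_3381	PP_3381	–	ISPpu9, transposase	up
PP_3678	PP_3678	–	Hypothetical protein	up
PP_4025	PP_4025	L	ISPpu15, transposase Orf2	up
PP_4092	PP_4092	L	ISPpu15, transposase Orf1	up
PP_4401	bkdAA	C	3-Methyl-2-oxobutanoate dehydrogenase	up
PP_4402	bkdAB	C	2-Oxoisovalerate dehydrogenase subunit beta	up
PP_4504	PP_4504	U	Hypothetical protein	up
PP_4728	grpE	O	Heat shock protein GrpE	up
PP_5000	hslV	O	ATP-dependent protease peptidase subunit	up
PP_5001	hslU	O	ATP-dependent protease ATP-binding subunit HslU	up
PP_5403	PP_5403	–	Hypothetical protein	up
PP_0526	PP_0526	L	ISPpu10, transposase	down
PP_0700	PP_0700	P	FecR anti-FecI sigma factor	down
PP_4070	PP_4070	P	Hypothetical protein	down
PP_5306	exbB	U	Ferric siderophore transport system protein ExbB	down
PP_5307	exbD	U	Biopolymer transport protein ExbD	down
PP_5308	tonB	M	TonB family protein	down
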
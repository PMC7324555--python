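strain_id	total_reads	reads_chromosome	reads_plasmid	coverage_chromosome	coverage_plasmid
KT2440(RP4)	814192	787096	23413	38.2	116.9
1-L1	2381592	2332342	35673	113.2	178.1
1-L2	2913274	2842868	55932	138.0	279.2
1-L3	2496020	2440928	38417	118.5	191.8
2-L1	2013740	1970058	34353	95.6	171.5
2-L2	2464816	2403860	48305	116.7	241.1
2-L3	2198728	2135990	49680	103.7	248.0
1-S1	2072027	2009011	58799	26.5	81.3
1-S2	3769764	3642167	120704	56.4	197.9
1-S3	2785120	2696425	83563	39.1	127.3
2-S1	955558	919201	31970	16.5	61.8
2-S2	2862190	2760179	81144	41.7	126.6
2-S3	1311846	1248070	42166	60.6	210.5
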
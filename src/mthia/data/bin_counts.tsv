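bin	size	sites_with_variations	total_variations	excluded_sites	excluded_variations
2 > Cv >= 1.9	115	4	333	1	330
1.9 > Cv >= 1.5	150	31	158	0	0
1.5 > Cv >= 1	239	67	4182	0	0
1 > Cv >= 0	277	73	3216	0	0
Cv < 0	13	3	5	0	0
Not aligned	161	85	6666	0	0
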
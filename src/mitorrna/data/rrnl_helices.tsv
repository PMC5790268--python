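# Example rrnL helix template (honeybee/fruit-fly style model,
# CRW helix numbering). Anchor motifs are synthetic stand-ins for
# the conserved flanking motifs of the reference model; helix ids
# without a published CRW label are synthetic placeholders.
# gene: rrnL
# length: 1320
crw_id	domain	anchor5	anchor3	stem_min	stem_max	loop_min	loop_max	expected_center	max_mismatch
H31	I	AGGTTATGGG	CCCATAACCT	10	12	3	8	0.0114	2
H94	I	CAATCACCCA	TGGGTGATTG	10	12	3	8	0.0341	2
H156	I	CTCACCAGAC	GTCTGGTGAG	10	12	3	8	0.0568	2
H219	I	GTTACTTTCT	AGAAAGTAAC	10	12	3	8	0.0795	2
H281	I	CCATCCAAAG	CTTTGGATGG	10	12	3	8	0.1023	2
H344	I	GGGAAACGCT	AGCGTTTCCC	10	12	3	8	0.1250	2
H406	I	AATTAAACCC	GGGTTTAATT	10	12	3	8	0.1477	2
H469	I	CTAGATCAGC	GCTGATCTAG	10	12	3	8	0.1705	2
H531	I	GAATCTGCAT	ATGCAGATTC	10	12	3	8	0.1932	2
H594	II	GTTGTGAGGC	GCCTCACAAC	10	12	3	8	0.2159	2
H656	II	TTGCAAAGTT	AACTTTGCAA	10	12	3	8	0.2386	2
H719	II	CACGCCCACA	TGTGGGCGTG	10	12	3	8	0.2614	2
H781	II	GCTCAGCCAC	GTGGCTGAGC	10	12	3	8	0.2841	2
H837	II	AAACGATGTC	GACATCGTTT	10	12	3	8	0.3068	2
H906	II	TGATAGGGTC	GACCCTATCA	10	12	3	8	0.3295	2
H969	II	AATCATAGAA	TTCTATGATT	10	12	3	8	0.3523	2
H1031	II	ACATTACTCT	AGAGTAATGT	10	12	3	8	0.3750	2
H1094	II	CAAAACCAAG	CTTGGTTTTG	10	12	3	8	0.3977	2
H1156	II	CCGGTAATGC	GCATTACCGG	10	12	3	8	0.4205	2
H1219	IV	CGTCGGACCT	AGGTCCGACG	10	12	3	8	0.4432	2
H1281	IV	AAGCGTCTGA	TCAGACGCTT	10	12	3	8	0.4659	2
H1344	IV	AGAAACGTGC	GCACGTTTCT	10	12	3	8	0.4886	2
H1406	IV	ATACAAGGCA	TGCCTTGTAT	10	12	3	8	0.5114	2
H1469	IV	CTATTTCAAG	CTTGAAATAG	10	12	3	8	0.5341	2
H1531	IV	TAGACGCAAA	TTTGCGTCTA	10	12	3	8	0.5568	2
H1594	IV	GCCCTGCCCG	CGGGCAGGGC	10	12	3	8	0.5795	2
H1656	IV	GGACGACTCG	CGAGTCGTCC	10	12	3	8	0.6023	2
H1719	IV	AGGGTTCGCG	CGCGAACCCT	10	12	3	8	0.6250	2
H1755	IV	GCGACTTATA	TATAAGTCGC	10	12	3	8	0.6477	2
H1835	IV	ATTATCTCCA	TGGAGATAAT	10	12	3	8	0.6705	2
H1906	IV	ATATTATCAT	ATGATAATAT	10	12	3	8	0.6932	2
H1925	IV	GCACGGGCAT	ATGCCCGTGC	10	12	3	8	0.7159	2
H2031	IV	GTCTAGCTGG	CCAGCTAGAC	10	12	3	8	0.7386	2
H2064	IV	TCCCACCCGG	CCGGGTGGGA	10	12	3	8	0.7614	2
H2156	V	TTCGAGTACT	AGTACTCGAA	10	12	3	8	0.7841	2
H2219	V	AGATCGCGCT	AGCGCGATCT	10	12	3	8	0.8068	2
H2281	V	CTAGCATGGA	TCCATGCTAG	10	12	3	8	0.8295	2
H2359	V	GTAGGCGCGG	CCGCGCCTAC	10	12	3	8	0.8523	2
H2406	V	AACTCACGCG	CGCGTGAGTT	10	12	3	8	0.8750	2
H2469	V	CGTGGGTACG	CGTACCCACG	10	12	3	8	0.8977	2
H2507	V	GATTGCCTAA	TTAGGCAATC	10	12	3	8	0.9205	2
H2594	VI	TACGACCGGT	ACCGGTCGTA	10	12	3	8	0.9432	2
H2656	VI	GATTCCAGCT	AGCTGGAATC	10	12	3	8	0.9659	2
H2735	VI	TGTTTTCGGG	CCCGAAAACA	10	12	3	8	0.9886	2
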
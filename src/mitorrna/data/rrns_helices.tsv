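# Example rrnS helix template (honeybee/fruit-fly style model,
# CRW helix numbering). Anchor motifs are synthetic stand-ins for
# the conserved flanking motifs of the reference model; helix ids
# without a published CRW label are synthetic placeholders.
# gene: rrnS
# length: 790
crw_id	domain	anchor5	anchor3	stem_min	stem_max	loop_min	loop_max	expected_center	max_mismatch
H17	I	GATATCTCAT	ATGAGATATC	10	12	3	8	0.0550	2
H47	I	TTCGCACTGC	GCAGTGCGAA	10	12	3	8	0.1500	2
H885	II	TCCATCACTG	CAGTGATGGA	10	12	3	8	0.4000	2
H921	III	CTAATTGGAT	ATCCAATTAG	10	12	3	8	0.5300	2
H939	III	GAATTACCAA	TTGGTAATTC	10	12	3	8	0.6200	2
H1074	III	CACACATCCA	TGGATGTGTG	10	12	3	8	0.7200	2
H1399	IV	GTTCGTCCTC	GAGGACGAAC	10	12	3	8	0.8400	2
H1506	IV	GGATGTATTT	AAATACATCC	10	12	3	8	0.9400	2
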
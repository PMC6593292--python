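# Genotypes of 13 HLA-matched HSCT donor-recipient pairs across the
# 20-MiHA panel, in tabulated notation (het "X/Y", homozygote single
# letter, deletion locus Im/No).  First subject of each pair is the
# recipient.  pair_type: related (sibling donor) or unrelated.
pair_id	pair_type	role	sample_id	HER-2/NEU	HA-1/A2	HA-2	UTA2-1	LB-ADIR-1F	LB-CLYBL-1Y	C19ORF48	TRIM22	LB-PRCP-1D	LB-SSR1-1S	LB-WNK1-1I	T4A1	HA-8	LB-HIVEP1-1S	LB-NISCH-1A	UGT2B17/A2	LB-CCL4-1T	LB-NCAPD3-1Q	LB-NDC80-1P	WDR27-1L
p908/p909	related	recipient	p908	G/C	A	C/T	C/T	T	G	A	C	T	A	T	A	C	A	C/T	Im	T	C	G/C	A
p908/p909	related	donor	p909	G/C	G	C	C	C	G	A	C	T	A	G/T	A	G	A	T	Im	T	C	G/C	A
p207/p208	unrelated	recipient	p207	G	A	C	T	C	G	T	C	G/T	A	G/T	A/C	C	A	T	Im	T	C	G	A/G
p207/p208	unrelated	donor	p208	G	A/G	T	C	T	G	T	C	G/T	A/G	G/T	A	G/C	A/G	T	Im	T	C/T	G	A/G
p180/p181	unrelated	recipient	p180	C	A/G	C	C	C/T	G/T	A	C	T	G	G	A	C	A/G	T	No	A/T	C/T	G	A
p180/p181	unrelated	donor	p181	G/C	G	T	T	C/T	G	T	C	T	A	G/T	A/C	G/C	A	C/T	Im	T	C	G	A
p298/p299	unrelated	recipient	p298	G/C	G	C	C	C/T	G	A/T	C	T	A/G	G/T	A/C	G	A	C/T	Im	T	C	G	A
p298/p299	unrelated	donor	p299	G/C	A/G	C/T	C/T	C	G	A/T	C	T	A	G	A/C	G/C	A	C/T	Im	T	C	G	A/G
p444/p198	unrelated	recipient	p444	G	A/G	C	C/T	C	G	A/T	C	T	A/G	G/T	A	G/C	A	C	Im	T	C/T	G	A/G
p444/p198	unrelated	donor	p198	C	A	C/T	C/T	C/T	G	T	C	T	A/G	T	C	G	A	T	Im	T	C	G	A/G
p1031/p1032	unrelated	recipient	p1031	C	A/G	C/T	C	C	G	T	C	T	A/G	G/T	A/C	G	A	C/T	Im	T	C	G	A/G
p1031/p1032	unrelated	donor	p1032	C/G	G	T	C	T/C	G	T	C	T	A	G/T	A	G/C	A	C/T	N/O	A/T	C	G	A
p1138/p1139	related	recipient	p1138	G	A/G	C	C	C	G	A/T	C	G/T	A/G	G/T	A	G	A	C	Im	T	C	G	A
p1138/p1139	related	donor	p1139	C/G	A/G	C	C	C	G	A	C	G/T	A/G	G/T	A/C	G	A	C	Im	A/T	C	G	A
p1056/p1057	related	recipient	p1056	G	G	C	T/C	T	G	A/T	C	T	A	G	A	G/C	A	T	No	A	C	G	G
p1056/p1057	related	donor	p1057	C/G	G	C	T/C	C	G	T	C	G/T	A	G/T	C	G/C	A	T	No	A/T	C	G	G
p1136/p1137	related	recipient	p1136	G	A/G	C	T/C	C	G	A/T	C	T	A	G/T	C	G/C	A	T	Im	T	C/T	G	A/G
p1136/p1137	related	donor	p1137	G	A/G	C	T/C	T/C	G	T	C	T	A/G	G/T	C	G	A	T	Im	T	C	G/C	A
p1151/p1152	unrelated	recipient	p1151	C	A/G	C	T/C	C	G	A/T	C	T	A	G	A/C	G	A/G	C/T	Im	A/T	C	G/C	A
p1151/p1152	unrelated	donor	p1152	G	A/G	T	C	C	G	A/T	C	T	A/G	G	A	G/C	A	T	Im	T	C/T	G	A/G
p1161/p1162	unrelated	recipient	p1161	G	A/G	C/T	T/C	T/C	G	A/T	C	T	A/G	G/T	A/C	G/C	A	T	Im	T	C	G	A
p1161/p1162	unrelated	donor	p1162	C/G	A/G	C	T/C	T/C	G	A	C	T	A/G	G/T	A	G	A	T	Im	A/T	C/T	G	G
p1155/p1156	unrelated	recipient	p1155	C/G	A/G	T	C	C	G	T	C	T	A	G	A	G/C	A	T	No	T	C	G	A/G
p1155/p1156	unrelated	donor	p1156	C/G	A/G	C	T/C	T	G	A/T	C	T	A	T	A	G/C	A	C	Im	T	C	G	A/G
p1175/p1176	unrelated	recipient	p1175	G	A/G	C/T	C	C	G	T	C	T	A	T	A/C	G/C	A	T	Im	T	C	G/C	A
p1175/p1176	unrelated	donor	p1176	C/G	A/G	C	C	T/C	G	T	C	T	A	T	A	C	A	T	Im	T	C	G	A
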
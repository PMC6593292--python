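# Synthetic illustrative immunogenic-allele frequencies for the default
# 20-MiHA panel.  Back-calculated from the published per-locus unrelated
# mismatch probabilities by inverting p_mm = (1 - q^2) * q^2 (q = 1 - p)
# and taking the minor-immunogenic root.  Demo / smoke-test data only.
locus	p_imm
HER-2/NEU	0.255170
HA-1/A2	0.249503
HA-2	0.026751
UTA2-1	0.208488
LB-ADIR-1F	0.292893
LB-CLYBL-1Y	0.030230
C19ORF48	0.046125
TRIM22	0.009735
LB-PRCP-1D	0.190729
LB-SSR1-1S	0.249503
LB-WNK1-1I	0.216407
T4A1	0.152009
HA-8	0.157526
LB-HIVEP1-1S	0.120306
LB-NISCH-1A	0.179509
UGT2B17/A2	0.074597
LB-CCL4-1T	0.249503
LB-NCAPD3-1Q	0.079994
LB-NDC80-1P	0.228723
WDR27-1L	0.156121
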
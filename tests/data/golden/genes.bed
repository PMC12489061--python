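chr2	15886	16686	tandemA_g0	0	+
chr2	17086	17886	tandemA_g1	0	+
chr2	18286	19086	tandemA_g2	0	-
chr1	28959	30159	dispB_g0	0	+
chr1	43609	44809	dispB_g1	0	+
chr1	21110	21710	dispC_g0	0	-
chr1	25219	25819	dispC_g1	0	-
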
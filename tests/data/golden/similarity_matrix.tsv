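# paralogrisk v0.1.0
# theta=0.7 norm=max all_pairs=False
# threshold=0.7 norm=max
	tandemA_g0	tandemA_g1	tandemA_g2	dispB_g0	dispB_g1	dispC_g0	dispC_g1
tandemA_g0	1	0.91375	0.90125				
tandemA_g1	0.91375	1	0.91375				
tandemA_g2	0.90125	0.91375	1				
dispB_g0				1	0.965833		
dispB_g1				0.965833	1		
dispC_g0						1	0.785
dispC_g1						0.785	1
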
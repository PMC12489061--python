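# paralogrisk v0.1.0
# theta=0.7 norm=max all_pairs=False
gene_a	gene_b	similarity
tandemA_g0	tandemA_g1	0.91375
tandemA_g0	tandemA_g2	0.90125
tandemA_g1	tandemA_g2	0.91375
dispB_g0	dispB_g1	0.965833
dispC_g0	dispC_g1	0.785
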
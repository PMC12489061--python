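# paralogrisk v0.1.0
# mode=both speed=4000.0 min_exposure=300 margin=300
margin_bp	genome_fraction
300	0.018
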
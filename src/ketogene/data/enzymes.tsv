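# name	recognition	offset_top	offset_bottom
MnlI	CCTC	7	6
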
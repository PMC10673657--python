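>tasiARF_conserved TAS3-derived tasiARF core conserved between Arabidopsis and rice (literature consensus); override with --tasiarfs for other sets
TTCTTGACCTTGTAAGACCCC
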
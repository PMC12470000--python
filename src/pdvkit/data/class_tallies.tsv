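class_label	n_subjects	n_variants	n_sfari
dn_missense_pdv	100	43	11
dn_silent_pdv	100	19	4
inh_missense	50	7838	696
inh_silent	50	4526	506
inh_utr	50	14334	1167
inh_updownstream	25	8173	447
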
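start_codon	end_codon	label
1	30	helix 1
31	42	external loop 1
43	70	helix 2
71	82	internal loop 1
83	112	helix 3
113	134	external loop 2
135	162	helix 4
163	174	internal loop 2
175	204	helix 5
205	216	external loop 3
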
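token	atc4	nutraceutical	otc
drugA	N03AX	0	0
drugB	N03AX	0	0
drugC	N05BA	0	0
drugD	A11GA	1	1
drugE	A04AA	0	0
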
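code	kind	weeks
Z3A.08	week	8
Z3A.20	week	20
Z3A.30	week	30
Z3A.32	week	32
Z3A.36	week	36
Z3A.38	week	38
Z3A.39	week	39
Z3A.40	week	40
Z3A.41	week	41
Z3A.42	week	42
O80	delivery
O82	delivery
Z37.0	delivery
Z33.1	marker
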
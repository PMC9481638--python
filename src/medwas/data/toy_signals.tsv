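drug	phecode	n_case	n_control	n_exposed_case	n_exposed_control	beta	se	odds_ratio	p_value	bonferroni_significant	coincidence_rate	method
N03AA	331.0	100	1900	10	60	1.2259	0.35	3.407	1e-06	True	0.10	logit
N05BA	345.0	150	1850	6	40	0.6340	0.44	1.885	0.004	False	0.04	logit
N02AA	327.0	500	4500	50	300	-0.2231	0.16	0.8	1e-09	True	0.10	logit
V03AB	345.1	200	1800	4	25	0.6419	0.52	1.9	0.001	False	0.02	logit
A04AA	331.0	100	1900	5	40	0.9163	0.47	2.5	0.0005	False	0.05	logit
A11GA	345.0	150	1850	9	42	1.0986	0.36	3.0	0.0001	False	0.06	logit
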
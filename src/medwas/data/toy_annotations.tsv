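drug	drug_original_indication	fda_class	trimester_of_prescription	intrapartum_or_immediate_postpartum	duration_of_prescription_days	perinatally_plausible_phenotype	nutraceutical_or_otc	sparsely_prescribed_regionally
N03AA	epilepsy	C	1,2,3	no	270	yes	no	no
N05BA	anxiety	unknown	1,2	no	60	yes	no	no
N02AA	pain	C	1,2,3	no	14	yes	no	no
V03AB	antidote	C	1	no	7	yes	no	yes
A04AA	nausea	C	1,2,3	yes	3	yes	no	no
A11GA	vitamin supplement	A	1,2,3	no		yes	yes	no
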
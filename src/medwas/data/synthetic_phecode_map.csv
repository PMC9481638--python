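icd,vocabulary,phecode,exclusion_range,label
A10.0,ICD10,100.0,100-100.99,synthetic phenotype alpha
A10.1,ICD10,100.0,100-100.99,synthetic phenotype alpha
A15.0,ICD10,100.5,100-100.99,synthetic phenotype alpha-sub
B20.0,ICD10,200.0,200.0,synthetic phenotype beta
B20.1,ICD10,200.0,200.0,synthetic phenotype beta
B21.0,ICD10,200.1,,synthetic phenotype beta-sub
C30.0,ICD10,300.0,,synthetic phenotype gamma
C30.1,ICD10,300.0,,synthetic phenotype gamma
C30.2,ICD10,300.0,,synthetic phenotype gamma
D40.0,ICD10,400.0,,synthetic phenotype delta
250.00,ICD9,100.0,100-100.99,synthetic phenotype alpha
V10.1,ICD9,400.0,,synthetic phenotype delta
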
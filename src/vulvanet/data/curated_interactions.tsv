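regulator	target	sign
LIN-3	MPK-1	activation
LIN-12i	MPK-1	inhibition
MPK-1	LIN-39	activation
LIN-39	LIN-39	activation
LIN-39	LIN-12m	activation
LIN-12i	LIN-12m	activation
MPK-1	LIN-12m	inhibition
CDK-4/CYD-1	LIN-12m	activation
LS	LIN-12i	activation
LIN-12m	LIN-12i	activation
LIN-12i	LIN-12i	activation
LIN-3	LIN-12i	ambiguous
CDK-2/CYE-1	LIN-12i	activation
CDK-1/CYB-3	LIN-12i	inhibition
MPK-1	CKI-1	inhibition
CDK-4/CYD-1	CKI-1	inhibition
APC	CKI-1	activation
CDK-1/CYB-3	CKI-1	activation
LIN-35	EFL-1	inhibition
CDK-4/CYD-1	LIN-35	inhibition
CDK-2/CYE-1	LIN-35	inhibition
LIN-39	SCF	activation
APC	SCF	inhibition
CDK-2/CYE-1	SCF	activation
SCF	APC	inhibition
CDK-1/CYB-3	APC	activation
CKI-1	CDK-4/CYD-1	inhibition
SCF	CDK-4/CYD-1	inhibition
CDK-1/CYB-3	CDK-4/CYD-1	inhibition
EFL-1	CDK-2/CYE-1	activation
LIN-35	CDK-2/CYE-1	inhibition
CKI-1	CDK-2/CYE-1	inhibition
SCF	CDK-2/CYE-1	inhibition
CKI-1	CDK-1/CYB-3	inhibition
APC	CDK-1/CYB-3	inhibition
EFL-1	CDK-1/CYB-3	activation
CDK-4/CYD-1	CDK-1/CYB-3	inhibition
CDK-1/CYB-3	CDK-1/CYB-3	activation
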
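haplotype	serological_alleles	sources
H01	I8	NIU,WL1,WL7
H02	I2	Line6_1,UCD001,NIU,WL1,WL2,WL3,WL6,WL7
H03	I4,I8	UCD003,RHC,NIU,WL2,WL3,WL6,WL9
H04	I8	NIU
H05	.	WPR1
H06	.	UCD001
H07	.	RIR1
H08	.	RIR1
H10	I8	ADOL-15I5
H11	I3	Line7_2
H12	.	WL2
H13	.	WPR1
H14	.	WPR1
H15	.	WL1
H16	.	WL6
H17	.	WL6
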
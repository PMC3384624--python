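name	chem_class	carbons	double_bonds
Ala	amino_acid		
Arg	amino_acid		
Asn	amino_acid		
Asp	amino_acid		
Cit	amino_acid		
Gln	amino_acid		
Glu	amino_acid		
Gly	amino_acid		
His	amino_acid		
Ile	amino_acid		
Leu	amino_acid		
Lys	amino_acid		
Met	amino_acid		
Orn	amino_acid		
Phe	amino_acid		
Pro	amino_acid		
Ser	amino_acid		
Thr	amino_acid		
Trp	amino_acid		
Tyr	amino_acid		
Val	amino_acid		
Ac-Orn	biogenic_amine		
ADMA	biogenic_amine		
alpha-AAA	biogenic_amine		
Carnosine	biogenic_amine		
Creatinine	biogenic_amine		
DOPA	biogenic_amine		
Dopamine	biogenic_amine		
Histamine	biogenic_amine		
Kynurenine	biogenic_amine		
Met-SO	biogenic_amine		
Nitro-Tyr	biogenic_amine		
OH-Pro	biogenic_amine		
PEA	biogenic_amine		
Putrescine	biogenic_amine		
Sarcosine	biogenic_amine		
SDMA	biogenic_amine		
Serotonin	biogenic_amine		
Spermidine	biogenic_amine		
Spermine	biogenic_amine		
C0	acylcarnitine		
C2	acylcarnitine		
C3	acylcarnitine		
C3:1	acylcarnitine	3	1
C3-OH	acylcarnitine		
C4	acylcarnitine		
C4:1	acylcarnitine	4	1
C4-OH	acylcarnitine		
C5	acylcarnitine		
C5:1	acylcarnitine	5	1
C5:1-DC	acylcarnitine	5	1
C5-DC	acylcarnitine		
C5-M-DC	acylcarnitine		
C5-OH	acylcarnitine		
C6	acylcarnitine		
C6:1	acylcarnitine	6	1
C7-DC	acylcarnitine		
C8	acylcarnitine		
C9	acylcarnitine		
C10	acylcarnitine		
C10:1	acylcarnitine	10	1
C10:2	acylcarnitine	10	2
C12	acylcarnitine		
C12:1	acylcarnitine	12	1
C12-DC	acylcarnitine		
C14	acylcarnitine		
C14:1	acylcarnitine	14	1
C14:1-OH	acylcarnitine	14	1
C14:2	acylcarnitine	14	2
C14:2-OH	acylcarnitine	14	2
C16	acylcarnitine		
C16:1	acylcarnitine	16	1
C16:1-OH	acylcarnitine	16	1
C16:2	acylcarnitine	16	2
C16:2-OH	acylcarnitine	16	2
C16-OH	acylcarnitine		
C18	acylcarnitine		
C18:1	acylcarnitine	18	1
C18:1-OH	acylcarnitine	18	1
C18:2	acylcarnitine	18	2
lysoPC a C14:0	lysoPC	14	0
lysoPC a C16:0	lysoPC	16	0
lysoPC a C16:1	lysoPC	16	1
lysoPC a C17:0	lysoPC	17	0
lysoPC a C18:0	lysoPC	18	0
lysoPC a C18:1	lysoPC	18	1
lysoPC a C18:2	lysoPC	18	2
lysoPC a C20:3	lysoPC	20	3
lysoPC a C20:4	lysoPC	20	4
lysoPC a C24:0	lysoPC	24	0
lysoPC a C26:0	lysoPC	26	0
lysoPC a C26:1	lysoPC	26	1
lysoPC a C28:0	lysoPC	28	0
lysoPC a C28:1	lysoPC	28	1
PC aa C24:0	PC_aa	24	0
PC aa C26:0	PC_aa	26	0
PC aa C28:1	PC_aa	28	1
PC aa C30:0	PC_aa	30	0
PC aa C30:2	PC_aa	30	2
PC aa C32:0	PC_aa	32	0
PC aa C32:1	PC_aa	32	1
PC aa C32:2	PC_aa	32	2
PC aa C32:3	PC_aa	32	3
PC aa C34:1	PC_aa	34	1
PC aa C34:2	PC_aa	34	2
PC aa C34:3	PC_aa	34	3
PC aa C34:4	PC_aa	34	4
PC aa C36:0	PC_aa	36	0
PC aa C36:1	PC_aa	36	1
PC aa C36:2	PC_aa	36	2
PC aa C36:3	PC_aa	36	3
PC aa C36:4	PC_aa	36	4
PC aa C36:5	PC_aa	36	5
PC aa C36:6	PC_aa	36	6
PC aa C38:0	PC_aa	38	0
PC aa C38:3	PC_aa	38	3
PC aa C38:4	PC_aa	38	4
PC aa C38:5	PC_aa	38	5
PC aa C38:6	PC_aa	38	6
PC aa C40:1	PC_aa	40	1
PC aa C40:2	PC_aa	40	2
PC aa C40:3	PC_aa	40	3
PC aa C40:4	PC_aa	40	4
PC aa C40:5	PC_aa	40	5
PC aa C40:6	PC_aa	40	6
PC aa C42:0	PC_aa	42	0
PC aa C42:1	PC_aa	42	1
PC aa C42:2	PC_aa	42	2
PC aa C42:4	PC_aa	42	4
PC aa C42:5	PC_aa	42	5
PC aa C42:6	PC_aa	42	6
PC aa C38:1	PC_aa	38	1
PC ae C30:0	PC_ae	30	0
PC ae C30:1	PC_ae	30	1
PC ae C30:2	PC_ae	30	2
PC ae C32:1	PC_ae	32	1
PC ae C32:2	PC_ae	32	2
PC ae C34:0	PC_ae	34	0
PC ae C34:1	PC_ae	34	1
PC ae C34:2	PC_ae	34	2
PC ae C34:3	PC_ae	34	3
PC ae C36:0	PC_ae	36	0
PC ae C36:1	PC_ae	36	1
PC ae C36:2	PC_ae	36	2
PC ae C36:3	PC_ae	36	3
PC ae C36:4	PC_ae	36	4
PC ae C36:5	PC_ae	36	5
PC ae C38:0	PC_ae	38	0
PC ae C38:1	PC_ae	38	1
PC ae C38:2	PC_ae	38	2
PC ae C38:3	PC_ae	38	3
PC ae C38:4	PC_ae	38	4
PC ae C38:5	PC_ae	38	5
PC ae C38:6	PC_ae	38	6
PC ae C40:1	PC_ae	40	1
PC ae C40:2	PC_ae	40	2
PC ae C40:3	PC_ae	40	3
PC ae C40:4	PC_ae	40	4
PC ae C40:5	PC_ae	40	5
PC ae C40:6	PC_ae	40	6
PC ae C42:0	PC_ae	42	0
PC ae C42:1	PC_ae	42	1
PC ae C42:2	PC_ae	42	2
PC ae C42:3	PC_ae	42	3
PC ae C42:4	PC_ae	42	4
PC ae C42:5	PC_ae	42	5
PC ae C44:3	PC_ae	44	3
PC ae C44:4	PC_ae	44	4
PC ae C44:5	PC_ae	44	5
PC ae C44:6	PC_ae	44	6
SM C16:0	sphingomyelin	16	0
SM C16:1	sphingomyelin	16	1
SM C18:0	sphingomyelin	18	0
SM C18:1	sphingomyelin	18	1
SM C20:2	sphingomyelin	20	2
SM C22:3	sphingomyelin	22	3
SM C24:0	sphingomyelin	24	0
SM C24:1	sphingomyelin	24	1
SM C26:0	sphingomyelin	26	0
SM C26:1	sphingomyelin	26	1
SM (OH) C14:1	sphingomyelin	14	1
SM (OH) C16:1	sphingomyelin	16	1
SM (OH) C22:1	sphingomyelin	22	1
SM (OH) C22:2	sphingomyelin	22	2
SM (OH) C24:1	sphingomyelin	24	1
H1	hexose		
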
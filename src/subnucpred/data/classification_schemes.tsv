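# 20 reduced amino-acid alphabets (name, number of groups, groups left-to-right,
# groups separated by '|'). Three schemes are repaired to valid partitions of the
# 20 residues per their cited conventions: F-Vc4 (F added to the aromatic group,
# R to the basic-containing group), Normalized-vdW (C added to the small-volume
# group), Solvent-accessibility (standard buried/exposed/intermediate grouping).
name	k	groups
HP	2	ALIMFPWV|DENCQGSTYRHK
DHP	4	ALVIFWMP|STYCNGQ|KRH|DE
7-Cat	7	AGV|ILFP|YMTS|HNQW|RK|DE|C
20-Cat	20	A|G|V|I|L|F|P|Y|M|T|S|H|N|Q|W|R|K|D|E|C
ms	6	AVLIMC|WYHF|TQSN|RK|ED|GP
lesk	6	AST|CVILWYMPF|HQN|RK|ED|G
F-Ic4	7	AWM|GST|HPY|CVIFL|DNQ|ER|K
F-Ic2	9	AWM|GS|HPY|CVI|FL|DNQ|ER|K|T
F-IIIc4	9	ACV|HPL|DQ|S|ERGN|F|IMT|KW|Y
F-Vc4	8	AWHCF|G|LEPV|KYMTR|IN|Q|D|S
Murphy8	8	LVMIC|AG|ST|P|FYW|DENQ|KR|H
Murphy15	15	LVIM|C|A|G|S|T|P|FY|W|E|D|N|Q|KR|H
Letter12	12	LVIM|C|AG|ST|P|FY|W|ED|N|Q|KR|H
Hydrophobicity	3	RKEDQN|GASTPHY|CLVIMFW
Normalized-vdW	3	GASTPDC|NVEQIL|MHKFRYW
Polarity	3	LIFWCMVY|PATGS|HQRKNED
Polarizability	3	GASDT|CPNVEQIL|KMHFRYW
Charge	3	KR|ANCQGHILMFPSTWYV|DE
Secondary-structure	3	EALMQKRH|VIYCWFT|GNPSD
Solvent-accessibility	3	ALFCGIVW|RKQEND|MSPTHY
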
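residue_name	residue_seq
SER	2
THR	5
THR	8
ASP	21
THR	22
GLY	23
SER	24
GLN	28
LEU	31
GLN	35
HIS	38
LEU	39
HIS	42
HIS	46
LYS	48
ASP	49
HIS	50
HIS	51
SER	52
ARG	54
GLY	55
SER	61
GLN	62
ARG	64
LYS	65
TYR	69
LYS	73
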
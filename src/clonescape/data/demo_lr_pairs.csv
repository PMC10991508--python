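ligand,receptor,location
TNFSF10,TNFRSF10A,plasma_membrane
TNFSF10,TNFRSF10B,plasma_membrane
TNFSF14,LTBR,plasma_membrane
EFNA1,EPHA4,plasma_membrane
EFNA4,EPHA4,plasma_membrane
EFNB1,EPHA4,plasma_membrane
EFNB2,EPHB2,plasma_membrane
EFNB2,EPHB3,plasma_membrane
EFNB2,EPHB4,plasma_membrane
BMP7,BMPR1A,secreted
CDH1,IGF1R,plasma_membrane
CLCF1,IL6ST,secreted
FGF1,FGFR1,secreted
FGF1,FGFR2,secreted
FGF9,FGFR1,secreted
FGF9,FGFR3,secreted
FGF18,FGFR1,secreted
FGF18,FGFR2,secreted
IGF1,IGF1R,secreted
IGF2,IGF1R,secreted
IL11,IL11RA,secreted
INHBB,ACVR1B,secreted
LTB,CD40,plasma_membrane
LTB,LTBR,plasma_membrane
LTB,TNFRSF1A,plasma_membrane
WNT7A,FZD5,secreted
WNT7B,FZD5,secreted
S100A9,TLR4,secreted
SAA1,TLR2,secreted
CXCL10,CXCR3,secreted
CD55,ADGRE5,plasma_membrane
CD59,CD2,plasma_membrane
HSP90AA1,EGFR,secreted
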
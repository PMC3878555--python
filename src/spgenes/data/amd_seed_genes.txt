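# Known age-related macular degeneration (AMD) genes used as seeds.
# Curated from Retina International plus published association studies;
# identifiers are kept exactly as curated (no symbol normalisation).
ABCR
ADAMTS9
APOE
ARMS2
B3GALTL
C2
C3
CETP
CFB
CFH
CFH1
CFHR1
CFHR3
CFI
COL10A1
COL8A1
DDR1
ERCC6
FBLN5
FBLN6
FILIP1L
HMCN1
HTRA1
IER3
LIPC
LOC387715
QRX
RAD51B
RAXL1
SLC16A8
TGFBR1
TIMP3
TLR3
TLR4
TNFRSF10A
VEGFA
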
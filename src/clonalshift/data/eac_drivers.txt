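# Oesophageal-adenocarcinoma and pan-cancer driver genes used for
# driver-aware clustering inclusion and polyclonality detection.
# One symbol per line; replace with your own list as needed.
TP53
NOTCH1
ARID1A
CNTNAP5
PIK3CA
SMARCA4
CDKN2A
FBXW7
SMAD4
STAG2
KRAS
ACVR2A
PTEN
BAX
CTNNB1
SEMA5A
MYO18B
SF3B1
TAF1
KMT2D
PIK3R1
ERBB2
ERBB3
MUTYH
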
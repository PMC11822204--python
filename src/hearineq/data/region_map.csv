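country,region
DK,Northern
FI,Northern
SE,Northern
AT,Western
BE,Western
CH,Western
DE,Western
FR,Western
IE,Western
LU,Western
NL,Western
CY,Southern
ES,Southern
GR,Southern
IT,Southern
MT,Southern
PT,Southern
BG,Eastern
CZ,Eastern
EE,Eastern
HR,Eastern
HU,Eastern
LT,Eastern
LV,Eastern
PL,Eastern
RO,Eastern
SI,Eastern
SK,Eastern
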
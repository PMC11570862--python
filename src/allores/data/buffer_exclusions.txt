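# Hetero group names never considered candidate modulators
# (crystallization buffers, cryoprotectants, monoatomic ions).
HOH
WAT
H2O
DOD
SO4
PO4
GOL
EDO
PEG
PG4
PGE
1PE
P6G
MPD
ACT
DMS
FMT
CIT
TRS
EPE
MES
IMD
BME
ACE
EOH
IPA
NO3
CO3
NH4
NA
CL
K
MG
CA
ZN
MN
FE
CU
NI
CO
CD
IOD
BR
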
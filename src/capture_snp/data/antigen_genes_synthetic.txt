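# 21-entry glioblastoma antigen gene list. Eight names are genes discussed in
# the study text; the remaining thirteen are SYNTHETIC placeholders standing in
# for the unavailable supplementary list.
SART1
DST
KIF5B
GPI
ZNF594
APBB1
ZNF324
ING4
GBMAG01
GBMAG02
GBMAG03
GBMAG04
GBMAG05
GBMAG06
GBMAG07
GBMAG08
GBMAG09
GBMAG10
GBMAG11
GBMAG12
GBMAG13
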
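iso3,region
AFG,South Asia
AGO,Eastern and Southern Africa
ARG,Latin America and the Caribbean
AUS,East Asia and the Pacific
BGD,South Asia
BEN,West and Central Africa
BOL,Latin America and the Caribbean
BRA,Latin America and the Caribbean
BFA,West and Central Africa
BDI,Eastern and Southern Africa
KHM,East Asia and the Pacific
CMR,West and Central Africa
CAN,North America
CAF,West and Central Africa
TCD,West and Central Africa
CHL,Latin America and the Caribbean
CHN,East Asia and the Pacific
COL,Latin America and the Caribbean
COD,West and Central Africa
COG,West and Central Africa
CIV,West and Central Africa
CUB,Latin America and the Caribbean
DEU,Europe and Central Asia
DJI,Middle East and North Africa
DOM,Latin America and the Caribbean
ECU,Latin America and the Caribbean
EGY,Middle East and North Africa
SLV,Latin America and the Caribbean
GNQ,West and Central Africa
ERI,Eastern and Southern Africa
ETH,Eastern and Southern Africa
FRA,Europe and Central Asia
GAB,West and Central Africa
GMB,West and Central Africa
GHA,West and Central Africa
GTM,Latin America and the Caribbean
GIN,West and Central Africa
GNB,West and Central Africa
HTI,Latin America and the Caribbean
HND,Latin America and the Caribbean
IND,South Asia
IDN,East Asia and the Pacific
IRN,Middle East and North Africa
IRQ,Middle East and North Africa
ITA,Europe and Central Asia
JPN,East Asia and the Pacific
JOR,Middle East and North Africa
KAZ,Europe and Central Asia
KEN,Eastern and Southern Africa
LAO,East Asia and the Pacific
LBN,Middle East and North Africa
LSO,Eastern and Southern Africa
LBR,West and Central Africa
LBY,Middle East and North Africa
MDG,Eastern and Southern Africa
MWI,Eastern and Southern Africa
MYS,East Asia and the Pacific
MLI,West and Central Africa
MRT,West and Central Africa
MEX,Latin America and the Caribbean
MNG,East Asia and the Pacific
MAR,Middle East and North Africa
MOZ,Eastern and Southern Africa
MMR,East Asia and the Pacific
NPL,South Asia
NIC,Latin America and the Caribbean
NER,West and Central Africa
NGA,West and Central Africa
PAK,South Asia
PNG,East Asia and the Pacific
PER,Latin America and the Caribbean
PHL,East Asia and the Pacific
RUS,Europe and Central Asia
RWA,Eastern and Southern Africa
SEN,West and Central Africa
SLE,West and Central Africa
SOM,Eastern and Southern Africa
ZAF,Eastern and Southern Africa
SSD,Eastern and Southern Africa
ESP,Europe and Central Asia
LKA,South Asia
SDN,Middle East and North Africa
TZA,Eastern and Southern Africa
THA,East Asia and the Pacific
TGO,West and Central Africa
TUR,Europe and Central Asia
UGA,Eastern and Southern Africa
UKR,Europe and Central Asia
GBR,Europe and Central Asia
USA,North America
UZB,Europe and Central Asia
VEN,Latin America and the Caribbean
VNM,East Asia and the Pacific
YEM,Middle East and North Africa
ZMB,Eastern and Southern Africa
ZWE,Eastern and Southern Africa
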
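l3_code,country
AGE,Argentina
ALB,Albania
ANG,Angola
AUT,Austria
BER,Bermuda
BOL,Bolivia
BOT,Botswana
BZN,Brazil
BUL,Bulgaria
BUR,Burkina Faso
CMN,Cameroon
CHN,China North-Central
CLM,Colombia
CON,"Congo, Republic of"
COS,Costa Rica
CPP,South Africa
CUB,Cuba
ECU,Ecuador
EGY,Egypt
ETH,Ethiopia
FRA,France
GAB,Gabon
GER,Germany
GHA,Ghana
GRB,Great Britain
GRC,Greece
IND,India
ITA,Italy
IVO,Ivory Coast
JAM,Jamaica
KEN,Kenya
MDG,Madagascar
MLW,Malawi
MOZ,Mozambique
NAM,Namibia
NGA,Nigeria
NWG,New Guinea
PER,Peru
POR,Portugal
SPA,Spain
SUD,Sudan
SWZ,Eswatini
TAN,Tanzania
TVL,South Africa
UGA,Uganda
VEN,Venezuela
ZAM,Zambia
ZAI,"Congo, Democratic Republic of"
ZIM,Zimbabwe
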
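symbol,pdb_id,ppi_degree
14-3-3,4IHL,27
ADYCA,4CLT,1
AKT,4GV1,53
AMPK,2UV4,20
CAMKK2,2ZV2,3
eIF4E,4TPW,
EP300,3BIY,
ERK1/2,4ZZN,39
GRB2,3C7I,
GSK3,1Q5K,29
HPH,4BQY,
KEAP1,4IQK,3
MDM2,4OGN,11
MEK,3EQI,14
mTOR,3FAP,55
NAMPT,4O13,2
NQO2,1SG0,0
p53,2VUK,
PARG,4B1H,1
PARP1,4ZZZ,8
PDE4B,4KP6,2
PDK1,5ACK,29
PGDH,2GDZ,0
PGES,4YL1,
PI3K,4L23,
PIN1,3I6C,7
PKC_alpha,4RA4,31
PLA2,3U8D,
PP1A,3E7B,8
PP2A,2IE4,18
PPAR_gamma,3U9Q,
PTEN,1D5R,32
Rac1,1MH1,18
Raf,4XV9,13
Rap1a,4KVG,15
Ras,3K8Y,28
Rheb,3T5G,24
RhoA,1KMQ,19
S6K1,2Z7R,30
SGK1,3HDM,25
SIRT6,3ZG6,4
SOS,4NYJ,
TNFR,1FT4,5
tyrRS,4Q93,1
ULK1,4WNO,10
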
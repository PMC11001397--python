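residue,rotamer,chi1,chi2,chi3,chi4,frequency
SER,p,62,,,,0.48
SER,t,-177,,,,0.22
SER,m,-65,,,,0.29
CYS,p,62,,,,0.23
CYS,t,-177,,,,0.26
CYS,m,-65,,,,0.50
THR,p,62,,,,0.49
THR,t,-175,,,,0.07
THR,m,-65,,,,0.43
PRO,endo,30,,,,0.44
PRO,exo,-29,,,,0.43
VAL,p,63,,,,0.06
VAL,t,175,,,,0.73
VAL,m,-60,,,,0.20
ILE,pt,62,170,,,0.13
ILE,tt,-177,166,,,0.02
ILE,tp,-177,66,,,0.02
ILE,mt,-65,170,,,0.60
ILE,mm,-65,-60,,,0.15
LEU,pp,62,80,,,0.01
LEU,tp,-177,65,,,0.29
LEU,tt,-172,145,,,0.02
LEU,mt,-65,175,,,0.59
LEU,mp,-85,65,,,0.02
ASP,p-10,62,-10,,,0.16
ASP,t0,-177,0,,,0.21
ASP,t70,-177,65,,,0.06
ASP,m-20,-70,-15,,,0.51
ASN,p-10,62,-10,,,0.07
ASN,p30,62,30,,,0.09
ASN,t-20,-174,-20,,,0.12
ASN,t30,-177,30,,,0.15
ASN,m-40,-65,-40,,,0.29
ASN,m-80,-65,-75,,,0.08
ASN,m120,-65,120,,,0.05
GLU,pt-20,62,180,-20,,0.05
GLU,pm0,70,-80,0,,0.02
GLU,tp30,-177,65,30,,0.06
GLU,tt0,-177,177,0,,0.24
GLU,tm-20,-177,-80,-25,,0.02
GLU,mp0,-65,85,0,,0.06
GLU,mt-10,-67,177,-10,,0.35
GLU,mm-40,-65,-58,-40,,0.12
GLN,pt20,62,180,20,,0.04
GLN,tp-100,-177,65,-100,,0.02
GLN,tp60,-177,65,60,,0.07
GLN,tt0,-177,177,0,,0.16
GLN,mp0,-65,85,0,,0.05
GLN,mt-30,-67,180,-25,,0.38
GLN,mm-40,-65,-60,-40,,0.08
GLN,mm100,-65,-60,100,,0.05
MET,ptp,62,180,75,,0.02
MET,ptm,62,180,-75,,0.02
MET,tpp,-177,65,75,,0.05
MET,tpt,-177,65,180,,0.02
MET,ttp,-177,180,75,,0.05
MET,ttt,-177,180,180,,0.03
MET,ttm,-177,180,-75,,0.07
MET,mtp,-67,180,75,,0.12
MET,mtt,-67,180,180,,0.10
MET,mtm,-67,180,-75,,0.11
MET,mmp,-65,-65,103,,0.02
MET,mmt,-65,-65,180,,0.04
MET,mmm,-65,-65,-70,,0.19
LYS,ptpt,62,180,68,180,0.01
LYS,pttp,62,180,180,65,0.01
LYS,pttt,62,180,180,180,0.02
LYS,pttm,62,180,180,-65,0.01
LYS,tptt,-177,68,180,180,0.02
LYS,ttpt,-177,180,68,180,0.02
LYS,tttp,-177,180,180,65,0.03
LYS,tttt,-177,180,180,180,0.13
LYS,tttm,-177,180,180,-65,0.03
LYS,ttmt,-177,180,-68,180,0.02
LYS,mptt,-90,68,180,180,0.01
LYS,mtpt,-67,180,68,180,0.02
LYS,mttp,-67,180,180,65,0.03
LYS,mttt,-67,180,180,180,0.20
LYS,mttm,-67,180,180,-65,0.03
LYS,mtmt,-67,180,-68,180,0.02
LYS,mmtt,-62,-68,180,180,0.05
LYS,mmtm,-62,-68,180,-65,0.01
LYS,mmmt,-62,-68,-68,180,0.01
ARG,ptt85,62,180,180,85,0.01
ARG,ptt180,62,180,180,180,0.01
ARG,tpt85,-177,65,180,85,0.01
ARG,ttp80,-177,180,65,80,0.02
ARG,ttt85,-177,180,180,85,0.02
ARG,ttt180,-177,180,180,180,0.04
ARG,ttt-85,-177,180,180,-85,0.02
ARG,ttm105,-177,180,-65,105,0.01
ARG,mtp85,-67,180,65,85,0.02
ARG,mtp180,-67,180,65,180,0.03
ARG,mtt85,-67,180,180,85,0.04
ARG,mtt180,-67,180,180,180,0.08
ARG,mtt-85,-67,180,180,-85,0.04
ARG,mtm180,-67,180,-65,180,0.03
ARG,mtm-85,-67,180,-65,-85,0.03
ARG,mmt180,-62,-68,180,180,0.03
ARG,mmm180,-62,-68,-65,180,0.02
HIS,p-80,62,-75,,,0.09
HIS,p80,62,80,,,0.04
HIS,t-170,-177,-165,,,0.05
HIS,t-80,-177,-80,,,0.11
HIS,t60,-177,60,,,0.05
HIS,m-70,-65,-70,,,0.29
HIS,m170,-65,165,,,0.07
HIS,m80,-65,80,,,0.13
PHE,p90,62,90,,,0.13
PHE,t80,-177,80,,,0.33
PHE,m-85,-65,-85,,,0.44
PHE,m-30,-65,-30,,,0.09
TYR,p90,62,90,,,0.13
TYR,t80,-177,80,,,0.34
TYR,m-85,-65,-85,,,0.43
TYR,m-30,-65,-30,,,0.09
TRP,p-90,62,-90,,,0.11
TRP,p90,62,90,,,0.06
TRP,t-105,-177,-105,,,0.16
TRP,t90,-177,90,,,0.18
TRP,m-10,-65,-5,,,0.05
TRP,m95,-65,95,,,0.32
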
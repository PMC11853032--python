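gene	category
TERT	telomere_machinery
TERC	telomere_machinery
DKC1	telomere_machinery
TEP1	telomere_machinery
NHP2	telomere_machinery
NOP10	telomere_machinery
GAR1	telomere_machinery
NAF1	telomere_machinery
WRAP53	telomere_machinery
TERF1	telomere_machinery
TERF2	telomere_machinery
TERF2IP	telomere_machinery
TINF2	telomere_machinery
POT1	telomere_machinery
ACD	telomere_machinery
CTC1	telomere_machinery
STN1	telomere_machinery
TEN1	telomere_machinery
HMBOX1	telomere_machinery
ZBTB48	telomere_machinery
RTEL1	telomere_machinery
PINX1	telomere_machinery
TNKS	telomere_machinery
TNKS2	telomere_machinery
NVL	telomere_machinery
ATRX	telomere_topology
DAXX	telomere_topology
H3F3A	telomere_topology
SMC5	telomere_topology
SMC6	telomere_topology
NSMCE2	telomere_topology
TOP2A	telomere_topology
TOP3A	telomere_topology
BLM	telomere_topology
WRN	telomere_topology
RMI1	telomere_topology
RMI2	telomere_topology
RECQL4	telomere_topology
DNA2	telomere_topology
PIF1	telomere_topology
FANCM	telomere_topology
FANCD2	telomere_topology
FANCA	telomere_topology
SLX4	telomere_topology
SLX4IP	telomere_topology
H2AFX	damage_checkpoint
PARP1	damage_checkpoint
TP53	damage_checkpoint
RB1	damage_checkpoint
ATM	damage_checkpoint
ATR	damage_checkpoint
ATRIP	damage_checkpoint
MDC1	damage_checkpoint
CHEK1	damage_checkpoint
CHEK2	damage_checkpoint
TP53BP1	damage_checkpoint
MRE11	damage_checkpoint
RAD50	damage_checkpoint
NBN	damage_checkpoint
RPA1	damage_checkpoint
RPA2	damage_checkpoint
RPA3	damage_checkpoint
BRCA1	damage_checkpoint
BRCA2	damage_checkpoint
BARD1	damage_checkpoint
TOPBP1	damage_checkpoint
CLSPN	damage_checkpoint
RAD9A	damage_checkpoint
RAD17	damage_checkpoint
HUS1	damage_checkpoint
RAD51	tmm_effector
RAD52	tmm_effector
RAD54L	tmm_effector
RAD51B	tmm_effector
RAD51C	tmm_effector
RAD51D	tmm_effector
XRCC2	tmm_effector
XRCC3	tmm_effector
RAD51AP1	tmm_effector
PALB2	tmm_effector
BRIP1	tmm_effector
MUS81	tmm_effector
EME1	tmm_effector
GEN1	tmm_effector
ERCC1	tmm_effector
ERCC4	tmm_effector
POLD1	tmm_effector
POLD2	tmm_effector
POLD3	tmm_effector
POLD4	tmm_effector
PCNA	tmm_effector
RFC1	tmm_effector
LIG1	tmm_effector
FEN1	tmm_effector
PML	tmm_effector
MND1	tmm_effector
PSMC3IP	tmm_effector
SFR1	tmm_effector
SWI5	tmm_effector
EXO1	tmm_effector
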
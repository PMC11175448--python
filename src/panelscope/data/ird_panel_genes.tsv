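# gene symbols of the bundled panel
ABCA4
ADGRV1
AIPL1
BEST1
C8orf37
CA4
CACNA1F
CDH23
CDHR1
CEP290
CERKL
CFAP410
CHM
CLRN1
CNGA1
CNGA3
CNGB1
CNGB3
CRB1
CRX
CYP4V2
DHDDS
DRAM2
EYS
FAM161A
FSCN2
GNAT2
GRK1
GUCA1A
GUCY2D
IDH3B
IMPDH1
IMPG2
IQCB1
KCNV2
KLHL7
LRAT
MAK
MERTK
MYO7A
NMNAT1
NR2E3
NRL
NYX
PCARE
PDE6A
PDE6B
PDE6C
PDE6G
POC1B
PRCD
PROM1
PRPF3
PRPF31
PRPF6
PRPF8
PRPH2
RBP3
RDH12
RDH5
RGR
RGS9BP
RHO
RLBP1
ROM1
RP1
RP1L1
RP2
RP9
RPE65
RPGR
RPGRIP1
RS1
SAG
SEMA4A
SNRNP200
SPATA7
TOPORS
TTC8
TULP1
USH2A
ZNF513
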
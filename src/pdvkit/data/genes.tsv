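symbol	category	sfari_score	ar_only	coding
AASDH	B2	none	false	true
ABCB6	A3	none	false	true
ADK	A2	2	false	true
AGAP5	B0	2	false	true
AHNAK	A2	2	false	true
ANK2	A1	1	false	true
APBB1	A2	2	false	true
APLP1	A3	none	false	true
AQP2	B0	none	false	true
ARHGAP8	B0	none	false	true
ARHGEF10	B0	2	false	true
ARHGEF18	B2	none	true	true
ARHGEF2	A3	3	false	true
ARPC1B	B1	none	true	true
ASPM	A2	2	false	true
ASXL1	B0	none	false	true
BFSP1	B1	none	false	true
CBARP	B0	none	false	true
CD101	B1	none	false	true
CELSR2	A3	none	false	true
CHRX	A1	none	false	true
CLCN4	A2	2	false	true
CLN8	A2	2	false	true
CNDP1	B0	none	false	true
CNOT11	B0	none	false	true
COL18A1	B3	none	false	true
COL4A4	B3	none	false	true
COL6A3	B0	none	false	true
COLEC12	B0	none	false	true
CORO1A	A1	1	false	true
CPVL	A3	none	false	true
CSMD1	B0	2	false	true
CTNNA3	B0	2	false	true
CXCR1	B0	none	false	true
DCAF4L2	B0	none	false	true
DCHS1	A3	none	true	true
DKK2	A3	none	false	true
DLG2	A2	2	false	true
DLGAP2	B0	2	false	true
DMXL1	A3	none	false	true
DOCK10	A3	none	false	true
DSCAM	A1	1	false	true
DYNLT3	A3	none	false	true
ECM1	B3	none	false	true
EFCAB13	B1	none	false	true
EFR3B	A3	none	false	true
EHBP1L1	B1	none	false	true
EP300	A1	1	false	true
ERAP1	B0	none	false	true
ERF	B0	none	false	true
FAM151A	B2	none	false	true
FAM178B	B2	none	false	true
FAM71E1	B3	none	false	true
FLNB	B2	none	false	true
FMN1	A3	none	false	true
GARRE1	B3	none	false	true
GDI2	B0	none	false	true
GHRHR	B1	none	true	true
GK2	B3	none	false	true
GLB1L3	B2	none	false	true
GLT6D1	B3	none	false	true
GPS1	A3	none	false	true
GRIK5	A2	2	false	true
HDLBP	A1	2	false	true
HECW1	A3	none	false	true
HMCN2	B2	none	false	true
HNRNPDL	B0	none	false	true
INS	B2	none	false	true
IQGAP2	B0	none	false	true
ITGB1BP1	B1	none	false	true
JPH3	A3	none	false	true
KBTBD13	B0	none	false	true
KCNA10	B1	none	false	true
KCNJ6	A3	none	false	true
KCTD13	B0	2	false	true
KDM5B	A1	1	true	true
KIDINS220	A3	none	false	true
KLHDC4	B1	none	false	true
LINC02203	B3	none	false	true
LRTM1	B0	none	false	true
MAP4K1	A3	3	false	true
MAPK3	B0	2	false	true
MAST3	A2	none	false	true
MCPH1	B0	2	false	true
MEIOB	B2	none	false	true
MGA	B3	none	false	true
MLXIPL	A3	none	false	true
MOGAT3	B3	none	false	true
MRPL27	A3	none	false	true
MT-ATP6	A1	1	false	true
MT-CO1	A1	1	false	true
MT-CO3	A1	1	false	true
MT-CYB	A1	1	false	true
MT-ND5	A1	1	false	true
MT-RNR2	A1	1	false	true
MTCL1	B0	none	false	true
MUC12	A2	2	false	true
MYBPC2	B3	none	false	true
MYH7	B0	none	false	true
MYLK	A3	3	false	true
MYO5B	B0	none	false	true
NKX1-1	A3	none	false	true
NNAT	B0	none	false	true
NPAS3	A3	none	false	true
NR1I2	B2	none	false	true
OPRK1	A3	none	false	true
OR6P1	B2	none	false	true
OXLD1	B2	none	false	true
PDCD5	B1	none	false	true
PLEKHH2	B0	none	false	true
PLOD3	B1	none	true	true
POLD1	B0	none	false	true
PPFIA2	B0	none	false	true
PRODH	A2	2	false	true
PSIP1	A3	none	false	true
PTGFR	B0	none	false	true
PTPRS	A3	none	false	true
RACK1	B0	none	false	true
REGION16P11D	B3	none	false	true
RFXANK	B0	none	true	true
RIMS1	A1	none	false	true
RMND5B	A3	none	false	true
RPRD2	A3	none	false	true
SCNN1A	B2	none	false	true
SEC16A	A3	none	false	true
SERPINB3	B2	none	false	true
SETD1A	A1	1	false	true
SETDB2	A2	2	false	true
SEZ6L2	B0	2	false	true
SH3RF1	A3	3	false	true
SHANK3	A1	1	false	true
SHROOM2	A3	none	false	true
SLC12A1	B0	none	false	true
SLC4A11	B0	none	true	true
SLC4A4	A3	none	true	true
SLC4A5	A3	none	false	true
SLC4A8	A3	none	false	true
SLC6A1	A1	1	false	true
SMC4	B0	none	false	true
SMCHD1	B2	none	false	true
SNAPC3	A3	none	false	true
SPIB	B3	none	false	true
STAB1	B0	none	false	true
STKLD1	B3	none	false	true
TAOK2	B0	2	false	true
TARS2	B3	none	false	true
TBC1D3I	B2	none	false	true
TBPL1	B1	none	false	true
TMEFF1	A3	none	false	true
TNFRSF25	B1	none	false	true
TOX	B0	none	false	true
TRPV4	A3	none	false	true
TTN	A2	2	false	true
TWF2	B0	none	false	true
TYK2	A3	none	true	true
UNKL	B0	none	false	true
USP20	A3	none	false	true
VPS13B	A1	1	true	true
WDR1	B0	none	true	true
ZNF300	B1	none	false	true
ZNF516	B0	none	false	true
ZNF865	B0	none	false	true
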
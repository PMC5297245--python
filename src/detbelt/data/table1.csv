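protein,topology,detergent,step,prot_uM,det_mM,mol_per_mol,err
SERCA1a,10 TMS monomer,DDM,SEC,6.03,0.934,155,27
BmrA,2x6 TMS homodimer,FC12,IMAC,12.3,5.7,463,18
BmrA,2x6 TMS homodimer,FC12,IMAC (2),2.7,1.2,457,17
BmrA,2x6 TMS homodimer,FC12,SEC,8.4,4.9,589,60
BmrA,2x6 TMS homodimer,DDM,IMAC,7.5,2.5,328,8
BmrA,2x6 TMS homodimer,DDM,SEC (peak average),9.5,3.7,412,40
BmrA,2x6 TMS homodimer,DDM,SEC,11.9,1.6,399,30
BmrA,2x6 TMS homodimer,LMNG,IMAC (pool),2.5,0.5,176,28
BmrA,2x6 TMS homodimer,LMNG,IMAC,4.4,0.8,138,11
BmrA,2x6 TMS homodimer,LMNG,SEC (peak average),4.4,0.9,157,13
BmrA,2x6 TMS homodimer,LMNG,SEC,5.9,0.9,167,10
BmrCD,6+6 TMS heterodimer,DDM,IMAC,34.5,15.9,459,12
BmrCD,6+6 TMS heterodimer,DDM,SEC,2.5,1.1,444,12
LacY,12 TMS monomer,DDM,SEC,12.2,4.7,383,27
hAAC1,6 TMS monomer,FC12,SEC,27.0,4.3,157,22
OprM,beta-barrel trimer,DDM,SEC,38.0,11.4,300,6
OprM,beta-barrel trimer,OG,SEC,4.84,1.77,364,70
hP2Y1r,7 TMS monomer,DDM,Desalting,27.8,6.2,223,6
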
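name,formula,adduct,mw_avg,matrix
DDM,C24H46O11,M+Na,510.62,DHBA
DDM-d25,C24H21D25O11,M+Na,535.77,DHBA
UDM,C23H44O11,M+Na,496.59,DHBA
OG,C14H28O6,M+Na,292.37,DHBA
LMNG,C47H88O22,M+Na,1005.19,THAP
DMNG,C43H80O22,M+Na,949.08,THAP
FC12,C17H38NO4P,M+H,351.46,CHCA
FC12-d38,C17D38NO4P,M+H,389.70,CHCA
FC14,C19H42NO4P,M+H,379.52,CHCA
CHAPS,C32H58N2O7S,M+Na,614.88,DHBA
CHAPSO,C32H58N2O8S,M+Na,630.88,DHBA
C4C10,C44H50O10,M+Na,738.87,CHCA
C4C12,C46H54O10,M+Na,766.92,CHCA
cholate,C24H40O5,M+H,408.57,9AA
deoxycholate,C24H40O4,M+H,392.57,9AA
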
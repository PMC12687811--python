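id,formula,pathway_tags
Trp,C11H12N2O2,de_novo
NFK,C11H12N2O4,de_novo
Kyn,C10H12N2O3,de_novo
3HK,C10H12N2O4,de_novo
3HAA,C7H7NO3,de_novo
QUIN,C7H5NO4,de_novo
NAD+,C21H27N7O14P2,de_novo;salvage;preiss_handler
NAM,C6H6N2O,salvage
MeNAM,C7H9N2O,methylation
NA,C6H5NO2,preiss_handler;microbial
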
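substrate,product,route,atoms_retained,redox_incorporation,requires_prior_nad
Trp,NFK,de_novo,C=11;H=12,false,false
NFK,Kyn,de_novo,C=10;H=11,false,false
Kyn,3HK,de_novo,C=10;H=11,false,false
3HK,3HAA,de_novo,C=7;H=7,false,false
3HAA,QUIN,de_novo,C=7;H=3,false,false
QUIN,NAD+,de_novo,C=6;H=3,false,false
NAM,NAD+,salvage,C=6;H=4,true,false
NAD+,NAM,consumption,C=6;H=4,false,false
NAM,MeNAM,methylation,C=6;H=4,false,false
NAM,NA,microbial,C=6;H=4,false,true
NA,NAD+,preiss_handler,C=6;H=3,true,false
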
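((((B_mori,B_mandarina)bombyx,M_sexta)bombycoidea,((S_litura,S_frugiperda)spodoptera,T_ni)noctuoidea,B_anynana)ditrysia_core,P_xylostella)root;
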
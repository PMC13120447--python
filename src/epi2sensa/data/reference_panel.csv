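code,name,cas,logp,pre_pro_hapten,in_vivo_class,ghs_subcat,vehicle,vrm_call,epi2sensa_call
DNCB,"2,4-Dinitrochlorobenzene",97-00-7,2.17,0,sensitizer,1A,AOO,positive,positive
PPD,p-Phenylenediamine,106-50-3,-0.39,1,sensitizer,1A,AOO,positive,positive
METOL,Metol,55-55-0,0.63,1,sensitizer,1A,DW,positive,positive
TCSA,Tetrachlorosalicylanilide,1154-59-2,5.87,0,sensitizer,1A,AOO,positive,positive
LG,Lauryl gallate,1166-52-5,6.9,1,sensitizer,1A,AOO,negative,negative
MHC,Methyl heptine carbonate,111-12-6,2.79,0,sensitizer,1A,AOO,positive,positive
ISOEU,Isoeugenol,97-54-1,3.04,1,sensitizer,1B,AOO,positive,positive
GLYOX,Glyoxal 40% solution in water,107-22-2,-0.08,0,sensitizer,1A,DW,positive,positive
ABIET,Abietic acid,514-10-3,3.92,1,sensitizer,1B,AOO,positive,positive
DBA,Dibutyl aniline,613-29-6,4.7,1,sensitizer,1B,AOO,positive,positive
ACA,Amyl cinnamic aldehyde,122-40-7,3.99,0,sensitizer,1B,AOO,positive,positive
BIT,Benzisothiazolinone,2634-33-5,0.8,0,sensitizer,1B,AOO,positive,positive
IMU,Imidazolidinyl urea,39236-46-9,-0.86,0,sensitizer,1B,DW,positive,positive
FARN,Farnesol,4602-84-0,4.91,0,sensitizer,1B,AOO,positive,positive
CET,Cetrimide,57-09-0,3.18,0,non_sensitizer,not_classified,EtOH50,negative,negative
LA,Lactic acid,50-21-5,-0.72,0,non_sensitizer,not_classified,DW,negative,negative
BBP,Benzyl butyl phthalate,85-68-7,4.84,0,non_sensitizer,not_classified,AOO,negative,negative
DEP,Diethyl phthalate,84-66-2,2.44,0,non_sensitizer,not_classified,AOO,positive,negative
HEX,Hexane,110-54-3,3.9,0,non_sensitizer,not_classified,AOO,negative,negative
IOH,1-Iodohexane,638-45-9,3.99,0,non_sensitizer,not_classified,AOO,positive,positive
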
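chemical,family,study_effect,study_direct,oecd_effect,oecd_equivocal_labs,lit_receptor,invivo_effect,in_oecd_set,in_invivo_set,invitro_ref_override
prochloraz,androgens,down,false,down,,positive,down,true,true,
forskolin,androgens,down,false,up,,unknown,unknown,true,false,
pfos,androgens,up,false,,,unknown,up,false,false,
aminoglutethimide,androgens,down,false,down,,unknown,up,true,true,
trilostane,androgens,down,false,up,,unknown,down,true,true,
hcg,androgens,nd,false,nd,,unknown,nd,true,true,
atrazine,androgens,nd,true,up,1,positive,nd,true,true,
letrozole,androgens,nd,true,down,,unknown,up,true,true,negative
molinate,androgens,nd,true,down,1,positive,nd,true,true,
bpa,androgens,nd,true,down,,positive,nd,true,true,
benomyl,androgens,nd,true,nd,,positive,nd,true,true,
butylparaben,androgens,nd,true,nd,,positive,nd,true,true,
cadmium_chloride,androgens,nd,false,,,nd,down,false,false,
prochloraz,estrogens,down,false,down,,unknown,down,true,true,
forskolin,estrogens,up,false,up,,unknown,unknown,true,false,
pfos,estrogens,up,false,,,unknown,down,false,false,
aminoglutethimide,estrogens,down,false,down,,unknown,down,true,true,
trilostane,estrogens,down_then_up,false,up,,unknown,down,true,true,
hcg,estrogens,nd,false,nd,,unknown,nd,true,true,
atrazine,estrogens,up,false,up,,nd,up,true,true,
letrozole,estrogens,down,false,down,,unknown,down,true,true,
molinate,estrogens,up,false,up,,nd,nd,true,true,
bpa,estrogens,nd,true,up,,positive,nd,true,true,
benomyl,estrogens,nd,false,nd,,nd,nd,true,true,
butylparaben,estrogens,nd,true,up,2,positive,nd,true,true,
cadmium_chloride,estrogens,nd,false,,,unknown,down,false,false,
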
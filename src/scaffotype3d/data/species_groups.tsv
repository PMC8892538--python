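# species	group	diploid_number
puma	felid	38
cheetah	felid	38
leopard	felid	38
tiger	felid	38
clouded_leopard	felid	38
dingo	canid	78
african_wild_dog	canid	78
red_fox	canid	34
black_bear	ursid	74
grizzly_bear	ursid	74
polar_bear	ursid	74
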
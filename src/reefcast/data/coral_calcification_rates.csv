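taxon,rate_kg_m2_yr,source
Orbicella faveolata,12.0,Florida Keys in-situ measurement
Porites astreoides,6.9,Florida Keys in-situ measurement
Siderastrea siderea,9.9,Florida Keys in-situ measurement
Orbicella annularis,10.4,package default (census-method magnitude)
Porites porites,4.7,package default (census-method magnitude)
Colpophyllia natans,9.4,package default (census-method magnitude)
Montastraea cavernosa,6.5,package default (census-method magnitude)
Diploria labyrinthiformis,8.6,package default (census-method magnitude)
Pseudodiploria strigosa,9.1,package default (census-method magnitude)
Agaricia agaricites,1.9,package default (census-method magnitude)
Millepora complanata,2.1,package default (census-method magnitude)
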
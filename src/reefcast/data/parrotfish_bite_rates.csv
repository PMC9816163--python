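species,phase,size_class,erosion_kg_fish_yr,source
Scarus iseri,initial,5-14,0.1,package default (census-method magnitude)
Scarus iseri,initial,15-24,0.6,package default (census-method magnitude)
Scarus iseri,terminal,15-24,1.1,package default (census-method magnitude)
Scarus taeniopterus,initial,5-14,0.1,package default (census-method magnitude)
Scarus taeniopterus,initial,15-24,0.7,package default (census-method magnitude)
Scarus taeniopterus,terminal,15-24,1.3,package default (census-method magnitude)
Scarus taeniopterus,terminal,25-34,3.8,package default (census-method magnitude)
Sparisoma aurofrenatum,initial,5-14,0.2,package default (census-method magnitude)
Sparisoma aurofrenatum,initial,15-24,1.2,package default (census-method magnitude)
Sparisoma aurofrenatum,terminal,15-24,2.4,package default (census-method magnitude)
Sparisoma aurofrenatum,terminal,25-34,6.5,package default (census-method magnitude)
Sparisoma viride,initial,5-14,1.5,package default (census-method magnitude)
Sparisoma viride,initial,15-24,21.0,package default (census-method magnitude)
Sparisoma viride,initial,25-34,64.0,package default (census-method magnitude)
Sparisoma viride,terminal,25-34,120.0,package default (census-method magnitude)
Sparisoma viride,terminal,35-44,250.0,package default (census-method magnitude)
Scarus guacamaia,terminal,35-44,310.0,package default (census-method magnitude)
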
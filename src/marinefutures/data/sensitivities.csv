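guild,end_rcp85,end_rcp26,channels,physical
phytoplankton,0.95,0.985,production,True
seagrass,1.5,1.12,production,False
mangrove,0.985,0.995,production,False
macrophyte,1.08,1.02,production,False
coral,0.6,0.72,consumption,False
zooplankton,1.0,1.0,consumption,False
benthic_invert,0.97,0.99,consumption,False
prawn,0.95,0.985,consumption,False
crab,0.97,0.99,consumption,False
planktivore,0.92,0.975,consumption,False
herbivore,1.0,1.0,consumption,False
reef_fish,0.7,0.9,consumption,False
estuarine_fish,0.92,0.975,consumption,False
barramundi,0.88,0.96,consumption,False
demersal_target,0.62,0.87,consumption,False
pelagic_fish,0.85,0.95,consumption,False
pelagic_shark,0.6,0.85,consumption,False
snubfin,0.78,0.85,consumption,False
dugong,1.25,1.08,consumption,False
turtle,1.3,1.09,consumption,False
seabird,1.0,1.0,consumption,False
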
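name,role,B0,PB,QB,unassim,F0_commercial,F0_recreational,site_attachment,wetland_associated,guild
phytoplankton,producer,40.0,180.0,0.0,0.0,0.0,0.0,0.0,False,phytoplankton
seagrass,producer,60.0,12.0,0.0,0.0,0.0,0.0,1.0,False,seagrass
mangroves,producer,40.0,8.0,0.0,0.0,0.0,0.0,1.0,False,mangrove
macrophytes,producer,25.0,15.0,0.0,0.0,0.0,0.0,1.0,False,macrophyte
corals,consumer,6.0,1.2,5.0,0.3,0.0,0.0,1.0,False,coral
zooplankton,consumer,20.0,25.0,80.0,0.3,0.0,0.0,0.0,False,zooplankton
benthic_inverts,consumer,30.0,4.0,14.0,0.35,0.0,0.0,0.8,False,benthic_invert
banana_prawns,consumer,4.0,5.0,20.0,0.3,0.6,0.0,0.7,True,prawn
other_prawns,consumer,3.0,4.5,18.0,0.3,0.4,0.0,0.7,True,prawn
crabs,consumer,5.0,2.5,9.0,0.3,0.1,0.05,0.8,False,crab
planktivorous_fish,consumer,12.0,1.8,8.0,0.25,0.0,0.0,0.3,False,planktivore
herbivorous_fish,consumer,8.0,1.5,7.0,0.3,0.0,0.02,0.9,False,herbivore
small_reef_fish,consumer,6.0,2.0,8.5,0.25,0.0,0.02,0.9,False,reef_fish
estuarine_fish,consumer,5.0,1.6,7.0,0.25,0.02,0.08,0.8,True,estuarine_fish
juv_barramundi,consumer,1.5,2.5,10.0,0.25,0.0,0.0,0.8,True,barramundi
barramundi,consumer,2.5,0.9,4.0,0.2,0.15,0.15,0.85,False,barramundi
snappers,consumer,3.0,0.8,3.8,0.2,0.2,0.1,0.8,False,demersal_target
emperors,consumer,2.5,0.85,4.0,0.2,0.15,0.1,0.8,False,demersal_target
threadfin,consumer,1.8,1.0,4.5,0.2,0.15,0.1,0.7,False,demersal_target
spanish_mackerel,consumer,1.2,0.7,3.5,0.2,0.12,0.08,0.2,False,pelagic_fish
large_reef_fish,consumer,2.0,0.6,3.0,0.2,0.05,0.1,0.95,False,reef_fish
pelagic_sharks,consumer,0.8,0.25,2.0,0.15,0.05,0.0,0.1,False,pelagic_shark
snubfin_dolphin,consumer,0.1,0.08,10.0,0.15,0.0,0.0,0.9,False,snubfin
dugong,consumer,0.5,0.1,9.0,0.3,0.0,0.0,0.8,False,dugong
turtles,consumer,0.4,0.15,3.5,0.3,0.0,0.0,0.6,False,turtle
seabirds,consumer,0.05,0.1,60.0,0.2,0.0,0.0,0.5,True,seabird
detritus,detritus,100.0,0.0,0.0,0.0,0.0,0.0,0.0,False,detritus
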
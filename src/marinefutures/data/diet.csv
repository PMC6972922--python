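prey,predator,fraction
zooplankton,corals,0.5
detritus,corals,0.5
phytoplankton,zooplankton,0.85
detritus,zooplankton,0.15
phytoplankton,benthic_inverts,0.1
seagrass,benthic_inverts,0.1
mangroves,benthic_inverts,0.1
macrophytes,benthic_inverts,0.2
detritus,benthic_inverts,0.5
zooplankton,banana_prawns,0.2
benthic_inverts,banana_prawns,0.2
detritus,banana_prawns,0.6
zooplankton,other_prawns,0.2
benthic_inverts,other_prawns,0.2
detritus,other_prawns,0.6
benthic_inverts,crabs,0.4
banana_prawns,crabs,0.05
other_prawns,crabs,0.05
detritus,crabs,0.5
phytoplankton,planktivorous_fish,0.1
zooplankton,planktivorous_fish,0.9
seagrass,herbivorous_fish,0.25
macrophytes,herbivorous_fish,0.6
detritus,herbivorous_fish,0.15
zooplankton,small_reef_fish,0.3
benthic_inverts,small_reef_fish,0.5
detritus,small_reef_fish,0.2
zooplankton,estuarine_fish,0.2
benthic_inverts,estuarine_fish,0.4
banana_prawns,estuarine_fish,0.1
other_prawns,estuarine_fish,0.1
detritus,estuarine_fish,0.2
zooplankton,juv_barramundi,0.2
benthic_inverts,juv_barramundi,0.3
banana_prawns,juv_barramundi,0.15
other_prawns,juv_barramundi,0.15
detritus,juv_barramundi,0.2
banana_prawns,barramundi,0.15
other_prawns,barramundi,0.15
crabs,barramundi,0.2
planktivorous_fish,barramundi,0.2
estuarine_fish,barramundi,0.3
benthic_inverts,snappers,0.2
crabs,snappers,0.2
planktivorous_fish,snappers,0.3
small_reef_fish,snappers,0.3
benthic_inverts,emperors,0.3
crabs,emperors,0.2
planktivorous_fish,emperors,0.25
small_reef_fish,emperors,0.25
benthic_inverts,threadfin,0.3
banana_prawns,threadfin,0.2
other_prawns,threadfin,0.2
estuarine_fish,threadfin,0.3
planktivorous_fish,spanish_mackerel,0.7
small_reef_fish,spanish_mackerel,0.2
estuarine_fish,spanish_mackerel,0.1
benthic_inverts,large_reef_fish,0.3
crabs,large_reef_fish,0.2
herbivorous_fish,large_reef_fish,0.1
small_reef_fish,large_reef_fish,0.4
planktivorous_fish,pelagic_sharks,0.3
herbivorous_fish,pelagic_sharks,0.1
estuarine_fish,pelagic_sharks,0.1
barramundi,pelagic_sharks,0.05
snappers,pelagic_sharks,0.1
emperors,pelagic_sharks,0.1
spanish_mackerel,pelagic_sharks,0.15
large_reef_fish,pelagic_sharks,0.1
banana_prawns,snubfin_dolphin,0.1
other_prawns,snubfin_dolphin,0.1
planktivorous_fish,snubfin_dolphin,0.3
small_reef_fish,snubfin_dolphin,0.2
estuarine_fish,snubfin_dolphin,0.3
seagrass,dugong,1.0
seagrass,turtles,0.6
macrophytes,turtles,0.2
benthic_inverts,turtles,0.2
banana_prawns,seabirds,0.1
other_prawns,seabirds,0.1
planktivorous_fish,seabirds,0.5
small_reef_fish,seabirds,0.1
estuarine_fish,seabirds,0.2
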
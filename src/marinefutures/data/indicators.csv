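indicator,class,group
target_fish,meta_group,snappers
target_fish,meta_group,emperors
target_fish,meta_group,threadfin
marine_mammals,meta_group,snubfin_dolphin
marine_mammals,meta_group,dugong
seabirds,meta_group,seabirds
tl23_fish,meta_group,planktivorous_fish
tl23_fish,meta_group,small_reef_fish
tl23_fish,meta_group,herbivorous_fish
sharks,keystone,pelagic_sharks
snubfin_dolphin,keystone,snubfin_dolphin
barramundi,keystone,barramundi
barramundi,keystone,juv_barramundi
large_reef_fish,keystone,large_reef_fish
corals,charismatic,corals
turtles,charismatic,turtles
dugong,charismatic,dugong
seagrass,habitat,seagrass
mangroves,habitat,mangroves
total_divergence,system,
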
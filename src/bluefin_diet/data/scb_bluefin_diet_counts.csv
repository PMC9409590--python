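broad_group,family,prey,lumped,n_2008,n_2009_14,n_2015_16,occ_2008,occ_2009_14,occ_2015_16,printed_pn_2008,printed_pn_2009_14,printed_pn_2015_16,printed_fo_2008,printed_fo_2009_14,printed_fo_2015_16
cephalopod,Argonautidae,Argonauta sp.,0,1,268,6,1,64,6,0.1,1.9,0.1,1.1,14.6,4.5
cephalopod,Enoploteuthidae,Abraliopsis sp.,0,590,11,18,68,1,3,29.6,0.1,0.4,77.3,0.2,2.2
cephalopod,Gonatidae,Gonatopsis sp.,0,1,6,4,1,4,3,0.1,0.0,0.1,1.1,0.9,2.2
cephalopod,Gonatidae,Gonatus sp.,0,22,744,33,8,96,9,1.1,5.2,0.7,9.1,21.9,6.7
cephalopod,Loliginidae,Doryteuthis opalescens,0,15,466,20,5,64,12,0.8,3.2,0.4,5.7,14.6,9.0
cephalopod,Octopodidae,Octopus bimaculatus,0,0,3,1,0,1,1,,0.0,0.0,,0.2,0.7
cephalopod,Octopodidae,Octopus rubescens,0,0,544,9,0,70,3,,3.8,0.2,,15.9,2.2
cephalopod,Octopoteuthidae,Octopoteuthis sp.,0,2,625,0,2,95,0,0.1,4.3,,2.3,21.6,
cephalopod,Onychoteuthidae,Onychoteuthis borealijaponica,0,22,565,16,16,81,12,1.1,3.9,0.3,18.2,18.5,9.0
cephalopod,Amphitretidae,Japetella heathi,1,2,21,0,2,9,0,0.1,0.1,,2.3,2.1,
cephalopod,Cranchiidae,Leachia sp.,1,0,0,1,0,0,1,,,0.0,,,0.7
cephalopod,Histioteuthidae,Histioteuthis heteropsis,1,2,5,0,1,3,0,0.1,0.0,,1.1,0.7,
cephalopod,Ommastrephidae,Dosidicus gigas,1,16,39,0,9,12,0,0.8,0.3,,10.2,2.7,
cephalopod,Unidentified squids,Unidentified squids,0,37,2380,60,4,188,18,1.9,16.6,1.2,4.5,42.8,13.4
fish,Carangidae,Trachurus symmetricus,0,1,1514,31,1,145,11,0.1,10.5,0.6,1.1,33.0,8.2
fish,Clupeidae,Sardinops sagax,0,4,246,44,3,71,18,0.2,1.7,0.9,3.4,16.2,13.4
fish,Engraulidae,Engraulis mordax,0,4,400,500,3,24,41,0.2,2.8,10.4,3.4,5.5,30.6
fish,Myctophidae,Ceratoscopelus townsendi,0,101,6,27,38,1,2,5.1,0.0,0.6,43.2,0.2,1.5
fish,Myctophidae,Diaphus theta,0,86,51,0,28,11,0,4.3,0.4,,31.8,2.5,
fish,Myctophidae,Nannobrachium ritteri,0,3,31,1,3,6,1,0.2,0.2,0.0,3.4,1.4,0.7
fish,Myctophidae,Protomyctophum crockeri,0,1,26,0,1,5,0,0.1,0.2,,1.1,1.1,
fish,Myctophidae,Stenobrachius leucopsaurus,0,147,22,0,33,10,0,7.4,0.2,,37.5,2.3,
fish,Myctophidae,Symbolophorus californiensis,0,0,36,1,0,14,1,,0.3,0.0,,3.2,0.7
fish,Myctophidae,Tarletonbeania crenularis,0,0,7,0,0,1,0,,0.0,,,0.2,
fish,Myctophidae,Triphoturus mexicanus,0,627,48,0,54,1,0,31.4,0.3,,61.4,0.2,
fish,Myctophidae,Myctophidae,0,1,0,0,1,0,0,0.1,,,1.1,,
fish,Scomberesocidae,Cololabis saira,0,4,294,11,3,57,5,0.2,2.0,0.2,3.4,13.0,3.7
fish,Scombridae,Scomber japonicus,0,0,594,4,0,79,2,,4.1,0.1,,18.0,1.5
fish,Sebastidae,Sebastes sp.,0,15,722,132,12,86,21,0.8,5.0,2.7,13.6,19.6,15.7
fish,Argentinidae,Argentina sialis,1,0,0,11,0,0,3,,,0.2,,,2.2
fish,Centrolophidae,Icichthys lockingtoni,1,0,1,0,0,1,0,,0.0,,,0.2,
fish,Exocoetidae,Cheilopogon pinnatibarbatus,1,0,0,2,0,0,2,,,0.0,,,1.5
fish,Labridae,Oxyjulis californica,1,0,0,3,0,0,2,,,0.1,,,1.5
fish,Merlucciidae,Merluccius productus,1,0,52,2,0,9,2,,0.4,0.0,,2.1,1.5
fish,Microstomatidae,Nansenia sp.,1,0,10,0,0,6,0,,0.1,,,1.4,
fish,Ophidiidae,Chilara taylori,1,0,20,16,0,9,10,,0.1,0.3,,2.1,7.5
fish,Paralepididae,Lestidiops ringens,1,0,21,0,0,8,0,,0.1,,,1.8,
fish,Paralepididae,Magnisudis atlantica,1,0,1,0,0,1,0,,0.0,,,0.2,
fish,Pleuronectidae,Pleuronichthys decurrens,1,0,9,0,0,2,0,,0.1,,,0.5,
fish,Pleuronectiformes,Pleuronectiformes,1,0,4,0,0,2,0,,0.0,,,0.5,
fish,Sciaenidae,Seriphus politus,1,0,2,0,0,1,0,,0.0,,,0.2,
fish,Scopelarchidae,Rosenblattichthys volucris,1,2,0,0,1,0,0,0.1,,,1.1,,
fish,Syngnathidae,Syngnathus californiensis,1,4,25,1,2,11,1,0.2,0.2,0.0,2.3,2.5,0.7
fish,Unidentified fishes,Unidentified fishes,0,37,243,67,23,77,24,1.9,1.7,1.4,26.1,17.5,17.9
crustacean,Hyperiidea,Phronima sp.,0,0,280,50,0,51,4,,1.9,1.0,,11.6,3.0
crustacean,Hyperiidea,Hyperiidea,0,0,3354,74,0,210,6,,23.3,1.5,,47.8,4.5
crustacean,Munididae,Pleuroncodes planipes,0,0,0,3591,0,0,113,,,74.5,,,84.3
crustacean,Unidentified Malacostraca,Unidentified Malacostraca,0,247,678,85,52,89,17,12.4,4.7,1.8,59.1,20.3,12.7
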
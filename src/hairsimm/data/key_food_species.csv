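category,trophic_class,species,d13C_mean,d13C_sd,d15N_mean,d15N_sd,C_mean,C_sd,N_mean,N_sd,n
Herbs,vegetable,Chenopodium bonus-henricus,-28.8,0.8,-2.3,1.4,46.2,1.0,5.1,1.4,3
Herbs,vegetable,Compositae,-31.0,1.9,-2.2,1.8,45.2,1.8,2.4,0.6,13
Herbs,vegetable,Graminacea,-29.7,1.4,-2.7,1.8,46.2,1.9,2.4,1.3,28
Herbs,vegetable,Trifolium thalii,-30.3,1.1,-1.0,0.6,45.7,1.4,3.4,0.6,9
Herbs,vegetable,Umbrelliferae,-30.2,1.9,-1.9,2.4,45.5,1.3,2.3,0.3,10
Hard masts,vegetable,Fagus sylvatica,-28.1,1.9,-0.8,2.0,54.6,4.0,3.7,0.8,6
Hard masts,vegetable,Quercus cerris,-27.2,2.0,-3.2,0.9,45.6,0.6,0.7,0.1,6
Hard masts,vegetable,Quercus pubescens,-27.6,0.8,0.4,1.7,44.9,1.0,1.4,1.2,6
Wild fleshy fruits,vegetable,Cornus mas,-28.2,2.1,-5.6,0.6,42.8,0.3,0.4,0.1,3
Wild fleshy fruits,vegetable,Crataegus monogyna,-26.7,0.8,-3.0,1.0,44.4,0.9,0.6,0.1,4
Wild fleshy fruits,vegetable,Fragaria vesca,-29.1,2.4,-3.0,2.7,48.8,1.5,1.4,0.3,5
Wild fleshy fruits,vegetable,Malus sylvestris,-26.9,0.9,-3.2,1.3,44.9,0.6,0.4,0.2,5
Wild fleshy fruits,vegetable,Prunus spinosa,-28.2,1.0,-1.9,2.5,48.9,1.8,0.7,0.4,4
Wild fleshy fruits,vegetable,Pyrus pyraster,-27.3,0.1,-1.9,1.3,46.7,3.0,0.6,0.0,3
Wild fleshy fruits,vegetable,Rhamnus alpina,-27.4,1.0,-2.4,2.0,45.2,0.7,0.7,0.1,7
Wild fleshy fruits,vegetable,Rosa canina,-26.2,0.8,-2.3,3.5,45.0,1.2,0.9,0.3,5
Wild fleshy fruits,vegetable,Rubus idaeus,-29.9,1.2,-3.6,1.6,51.0,1.3,1.3,0.2,4
Wild fleshy fruits,vegetable,Rubus ulmifolius,-28.6,0.9,-0.9,1.7,49.4,2.8,1.2,0.3,6
Cultivated fleshy fruits,vegetable,Ficus carica,-28.5,0.3,-1.5,0.2,45.4,1.3,1.0,0.2,3
Cultivated fleshy fruits,vegetable,Malus domestica,-25.8,1.5,0.5,2.3,43.5,0.3,0.4,0.2,4
Cultivated fleshy fruits,vegetable,Prunus domestica,-28.3,1.5,3.7,1.3,43.0,0.5,0.9,0.4,3
Cultivated fleshy fruits,vegetable,Pyrus communis,-26.9,0.6,0.1,2.3,42.7,0.7,0.3,0.1,6
Cultivated vegetables,vegetable,Cichorium intybus,-28.5,0.3,10.6,3.2,37.2,2.3,2.5,0.4,3
Cultivated vegetables,vegetable,Daucus carota,-26.4,1.0,4.4,0.5,40.7,1.5,1.4,0.2,3
Cultivated vegetables,vegetable,Eruca vesicaria,-29.0,0.3,10.5,0.7,34.7,4.0,4.2,0.7,3
Cultivated vegetables,vegetable,Lactuga sativa,-30.0,0.1,10.5,2.7,39.3,4.4,3.5,1.6,3
Ungulates,animal,Bos taurus,-25.5,0.2,2.2,0.6,49.3,1.1,3.6,0.2,1
Ungulates,animal,Capra hircus,-24.1,0.0,3.7,0.2,48.1,0.7,3.5,0.0,1
Ungulates,animal,Cervus elaphus,-26.3,1.0,3.9,1.4,53.2,6.6,5.2,3.5,3
Ungulates,animal,Ovis aries,-23.1,0.0,7.8,0.9,46.2,0.9,3.4,0.1,1
Ungulates,animal,Sus scrofa,-25.3,0.0,4.5,0.3,49.1,1.5,3.5,0.1,1
Formicidae,animal,Formicidae,-26.6,1.2,1.7,1.1,52.0,5.5,9.4,1.7,26
C4,vegetable,Zea mays,-11.9,0.4,4.3,1.5,45.6,0.5,17.4,2.3,3
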
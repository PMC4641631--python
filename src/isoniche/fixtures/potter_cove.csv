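taxon,site,size_class,trophic_group,storage,n_individuals,n_replicates,mean_d13C,sd_d13C,mean_d15N,sd_d15N,formalin_corrected
Suspended Particulate Matter,none,not_applicable,SPM,none,22,1,-26.08,1.17,0.45,1.17,false
Macroalgae,none,not_applicable,macroalgae,none,22,1,-25.03,5.45,3.08,0.85,false
Microphytobenthos,none,not_applicable,MPB,frozen,1,2,-13.15,0.35,4.90,0.14,false
Phytoplankton 200um,none,not_applicable,phytoplankton_200,frozen,5,1,-25.31,1.47,4.33,0.54,false
Phytoplankton 55um,none,not_applicable,phytoplankton_55,frozen,3,1,-23.41,0.85,4.69,0.34,false
Sediment 0-5cm,Faro,not_applicable,sediment,frozen,10,2,-20.81,1.21,3.26,0.77,false
Sediment 0-1cm,Faro,not_applicable,sediment,frozen,1,2,-18.72,0.56,3.35,0.19,false
Sediment 0-5cm,IslaD,not_applicable,sediment,frozen,10,1,-18.84,1.80,3.25,0.89,false
Sediment 0-1cm,IslaD,not_applicable,sediment,frozen,1,2,-17.84,1.06,3.86,0.67,false
Sediment 0-5cm,Creek,not_applicable,sediment,frozen,10,1,-22.54,1.09,4.01,0.68,false
Sediment 0-1cm,Creek,not_applicable,sediment,frozen,1,2,-21.53,1.60,4.55,1.00,false
Malacobelemnon daytoni,Faro,large_macrofauna,filter_suspension_feeder,formalin,1,3,-22.64,0.30,7.14,0.22,true
Molgula pedunculata,IslaD,large_macrofauna,filter_suspension_feeder,formalin,1,2,-23.57,0.01,4.69,0.00,true
Corella eumyota,IslaD,large_macrofauna,filter_suspension_feeder,formalin,1,3,-23.99,0.10,4.58,0.08,true
Cnemidocarpa verrucosa,IslaD,large_macrofauna,filter_suspension_feeder,formalin,1,2,-24.24,0.23,5.83,0.67,true
Ascidian,IslaD,large_macrofauna,filter_suspension_feeder,formalin,1,1,-25.48,0.00,3.52,0.00,true
Mysid,none,not_applicable,zooplankton,frozen,1,1,-21.36,0.00,6.10,0.00,false
Nototanaid MT1,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,7,2,-20.92,1.96,4.90,0.66,true
Nototanaid MT2,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,8,3,-15.48,0.86,4.80,0.20,true
Eudorella sp.,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,5,2,-17.05,0.07,7.65,0.07,true
Eudorella sp.,IslaD,small_macrofauna,deposit_feeder_omnivore,formalin,5,2,-16.45,1.06,7.05,0.21,true
Eudorella sp.,Creek,small_macrofauna,deposit_feeder_omnivore,formalin,5,2,-19.45,0.84,7.05,0.21,true
Dyastilis sp.,IslaD,small_macrofauna,deposit_feeder_omnivore,formalin,5,2,-21.80,0.14,5.70,0.00,true
Eudorella sp.,Faro,meiofauna,deposit_feeder_omnivore,frozen,8,2,-16.63,0.01,13.75,0.60,false
Eudorella sp.,Creek,meiofauna,deposit_feeder_omnivore,frozen,8,1,-14.07,0.00,10.07,0.00,false
Calanoid copepods,none,not_applicable,zooplankton,frozen,3,7,-24.19,1.10,6.77,0.38,false
Harpacticoids MT2,IslaD,meiofauna,bearing_ectosymbiont,frozen,40,1,-34.90,0.00,-2.60,0.00,false
Harpacticoids MT1,IslaD,meiofauna,deposit_feeder_omnivore,frozen,40,1,-20.05,0.00,10.34,0.00,false
Paraserolis polita,Faro,large_macrofauna,predator_omnivore,frozen,1,2,-16.65,1.06,12.10,0.56,false
Phoxocephalidae,Creek,small_macrofauna,scavenger_omnivore,formalin,3,5,-16.20,0.31,11.33,0.27,true
Phoxocephalidae,Faro,small_macrofauna,scavenger_omnivore,formalin,3,2,-14.38,0.75,7.83,0.04,true
Amphipod MT1,Faro,small_macrofauna,scavenger_omnivore,formalin,1,3,-17.61,0.00,10.59,0.01,true
Amphipods,IslaD,meiofauna,scavenger_omnivore,formalin,5,2,-19.71,1.60,8.99,0.70,true
Yoldia eightsi,Faro,large_macrofauna,deposit_feeder_omnivore,formalin,1,3,-11.81,0.84,8.75,0.42,true
Yoldia eightsi,Creek,large_macrofauna,deposit_feeder_omnivore,formalin,1,3,-11.76,0.81,8.12,0.27,true
Nematodes,Faro,meiofauna,deposit_feeder_omnivore,frozen,600,1,-17.99,0.00,8.60,0.00,false
Nematodes,IslaD,meiofauna,deposit_feeder_omnivore,frozen,600,1,-16.50,0.00,8.25,0.00,false
Nematodes,Creek,meiofauna,deposit_feeder_omnivore,frozen,600,1,-18.50,0.00,10.10,0.00,false
Aglaophamus trissophyllus,Creek+IslaD,large_macrofauna,predator_omnivore,formalin,1,3,-14.27,0.08,12.58,0.07,true
Barrukia cristata,Creek+IslaD,large_macrofauna,predator_omnivore,formalin,1,3,-16.96,0.17,11.74,0.06,true
Cerratulidae,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,5,6,-18.06,0.45,8.35,0.30,true
Cerratulidae,Creek,small_macrofauna,deposit_feeder_omnivore,formalin,5,3,-14.12,0.50,7.69,0.18,true
Spionidae,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,1,2,-18.27,0.27,8.64,0.34,true
Opheliidae,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,10,2,-19.35,0.42,11.52,1.42,true
Capitellidae,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,10,1,-15.49,0.00,12.62,0.00,true
Capitellidae,Creek,small_macrofauna,deposit_feeder_omnivore,formalin,5,2,-17.09,0.58,9.85,0.46,true
Maldanidae MT1,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,1,3,-15.89,0.06,10.34,0.70,true
Maldanidae MT2,Faro,small_macrofauna,deposit_feeder_omnivore,formalin,1,3,-19.68,0.14,9.64,0.35,true
Capitellidae,Faro,meiofauna,deposit_feeder_omnivore,formalin,5,3,-19.01,0.10,12.49,0.30,true
Cirratulidae MT1,Creek,meiofauna,deposit_feeder_omnivore,formalin,5,3,-18.30,0.03,7.58,0.04,true
Cirratulidae MT2,Creek,meiofauna,deposit_feeder_omnivore,formalin,10,1,-18.15,0.57,12.36,0.54,true
Orbiniidae,Faro,meiofauna,deposit_feeder_omnivore,formalin,5,3,-19.34,0.42,11.51,1.41,true
Cirratulidae,Faro,meiofauna,deposit_feeder_omnivore,formalin,5,3,-18.28,0.03,11.26,0.24,true
Ampharetidae,IslaD,small_macrofauna,deposit_feeder_omnivore,formalin,1,1,-15.90,0.84,8.10,1.14,true
Priapulus sp.,Faro,small_macrofauna,predator_omnivore,formalin,1,3,-17.99,0.44,10.70,0.49,true
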
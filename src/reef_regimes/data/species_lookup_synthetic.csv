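species,group,family,trophic,a,b,typical_tl_cm,schooling,excluded,exclusion_reason
Naso unicornis,browsers,Acanthuridae,herbivore,0.0286,2.85,35,0,0,
Kyphosus vaigiensis,browsers,Kyphosidae,herbivore,0.0170,3.02,30,1,0,
Calotomus carolinus,browsers,Scaridae,herbivore,0.0135,3.04,28,0,0,
Acanthurus nigrofuscus,grazers,Acanthuridae,herbivore,0.0392,2.79,15,0,0,
Ctenochaetus strigosus,grazers,Acanthuridae,herbivore,0.0355,2.88,14,0,0,
Zebrasoma flavescens,grazers,Acanthuridae,herbivore,0.0530,2.80,16,0,0,
Scarus psittacus,scrapers,Scaridae,herbivore,0.0139,3.05,22,1,0,
Chlorurus spilurus,scrapers,Scaridae,herbivore,0.0156,3.03,24,0,0,
Scarus rubroviolaceus,scrapers,Scaridae,herbivore,0.0131,3.07,40,0,0,
Caranx melampygus,predators,Carangidae,piscivore,0.0165,2.98,50,0,0,
Aprion virescens,predators,Lutjanidae,piscivore,0.0132,3.00,60,0,0,
Sphyraena barracuda,predators,Sphyraenidae,piscivore,0.0055,3.06,80,0,0,
Parupeneus multifasciatus,secondary_consumers,Mullidae,invertivore,0.0206,2.95,22,0,0,
Thalassoma duperrey,secondary_consumers,Labridae,invertivore,0.0107,3.05,14,0,0,
Chaetodon multicinctus,secondary_consumers,Chaetodontidae,corallivore,0.0395,2.87,10,0,0,
Mobula birostris,predators,Mobulidae,planktivore,0.0165,2.90,300,0,1,manta ray
Apogon kallopterus,secondary_consumers,Apogonidae,invertivore,0.0190,2.96,10,0,1,nocturnal
Decapterus macarellus,secondary_consumers,Carangidae,planktivore,0.0080,3.10,25,1,1,pelagic schooling
Eviota epiphanes,secondary_consumers,Gobiidae,invertivore,0.0120,3.00,3,0,1,cryptic benthic
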
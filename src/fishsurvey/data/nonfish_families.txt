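# Non-fish vertebrate family blocklist: reptile, amphibian, bird and mammal
# families seen as contaminants in institutionally mixed recordsets.
# Exact (case-insensitive) matches are always treated as erroneous records.
Accipitridae
Alligatoridae
Ambystomatidae
Anatidae
Anguidae
Ardeidae
Boidae
Bovidae
Bufonidae
Canidae
Castoridae
Cervidae
Charadriidae
Chelydridae
Colubridae
Corvidae
Cricetidae
Crocodylidae
Cryptobranchidae
Dasypodidae
Didelphidae
Elapidae
Emydidae
Felidae
Fringillidae
Gekkonidae
Geomyidae
Heteromyidae
Hylidae
Icteridae
Iguanidae
Kinosternidae
Laridae
Leporidae
Leptodactylidae
Microhylidae
Muridae
Mustelidae
Parulidae
Phasianidae
Phrynosomatidae
Phyllostomidae
Picidae
Plethodontidae
Procyonidae
Proteidae
Pythonidae
Ranidae
Salamandridae
Scaphiopodidae
Scincidae
Sciuridae
Scolopacidae
Sirenidae
Soricidae
Strigidae
Talpidae
Teiidae
Testudinidae
Trionychidae
Trochilidae
Turdidae
Tyrannidae
Ursidae
Vespertilionidae
Viperidae
Vireonidae
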
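# Valid fish family names (one per line). User-overridable by path.
Acanthuridae
Achiridae
Acipenseridae
Agonidae
Albulidae
Alepocephalidae
Amiidae
Ammodytidae
Anarhichadidae
Anguillidae
Antennariidae
Aplocheilidae
Apogonidae
Argentinidae
Ariidae
Atherinopsidae
Balistidae
Bathylagidae
Batrachoididae
Belonidae
Blenniidae
Bothidae
Callichthyidae
Callionymidae
Carangidae
Carcharhinidae
Catostomidae
Centrarchidae
Chaetodontidae
Characidae
Chimaeridae
Cichlidae
Clinidae
Clupeidae
Cobitidae
Congridae
Coryphaenidae
Cottidae
Cyclopteridae
Cyprinidae
Cyprinodontidae
Dactylopteridae
Dasyatidae
Diodontidae
Echeneidae
Eleotridae
Elopidae
Embiotocidae
Engraulidae
Ephippidae
Esocidae
Exocoetidae
Fistulariidae
Fundulidae
Gadidae
Gasterosteidae
Gerreidae
Gobiesocidae
Gobiidae
Gonostomatidae
Goodeidae
Gymnotidae
Haemulidae
Hemiramphidae
Hiodontidae
Holocentridae
Ictaluridae
Istiophoridae
Kyphosidae
Labridae
Labrisomidae
Lamnidae
Lepisosteidae
Liparidae
Lobotidae
Loricariidae
Lotidae
Lutjanidae
Macrouridae
Malacanthidae
Megalopidae
Merlucciidae
Molidae
Monacanthidae
Moronidae
Mugilidae
Mullidae
Muraenidae
Myctophidae
Myliobatidae
Myxinidae
Notacanthidae
Ogcocephalidae
Ophichthidae
Ophidiidae
Osmeridae
Ostraciidae
Paralichthyidae
Percichthyidae
Percidae
Percopsidae
Petromyzontidae
Pholidae
Pimelodidae
Pleuronectidae
Poeciliidae
Polynemidae
Polyodontidae
Pomacanthidae
Pomacentridae
Priacanthidae
Rajidae
Rivulidae
Salmonidae
Scaridae
Sciaenidae
Scomberesocidae
Scombridae
Scorpaenidae
Serranidae
Soleidae
Sparidae
Sphyraenidae
Sphyrnidae
Squalidae
Sternoptychidae
Stichaeidae
Stomiidae
Stromateidae
Syngnathidae
Synodontidae
Tetraodontidae
Trachichthyidae
Triglidae
Umbridae
Uranoscopidae
Xiphiidae
Zanclidae
Zoarcidae
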
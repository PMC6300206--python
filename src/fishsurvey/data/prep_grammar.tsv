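# Preparation-category synonym table: category <TAB> synonym.
# Synonyms are matched case-insensitively after token normalization; edit or
# override by path to teach the parser new provider dialects.
ethanol	etoh
ethanol	ethanol
ethanol	alcohol
ethanol	alc
ethanol	70% ethanol
ethanol	95% ethanol
ethanol	fluid
ethanol	wet
skeleton	skel
skeleton	skeleton
skeleton	skeletal
skeleton	dry skeleton
skeleton	skeletons
skeleton	bone
cleared_and_stained	c&s
cleared_and_stained	cs
cleared_and_stained	cleared and stained
cleared_and_stained	cleared & stained
cleared_and_stained	cleared/stained
cleared_and_stained	cleared
tissue	tissue
tissue	tissues
tissue	dna
tissue	frozen tissue
tissue	fin clip
tissue	muscle
formalin	formalin
formalin	formaldehyde
formalin	10% formalin
dried	dried
dried	dry
media	photo
media	photograph
media	photographs
media	image
media	digital image
media	x-ray
media	xray
media	radiograph
media	slide
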
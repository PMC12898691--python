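# Nine porphyria-associated genes (heme-biosynthesis enzymes plus HFE),
# HGNC symbols; example query set for users with a full profile matrix.
ALAS2
ALAD
HMBS
UROS
UROD
CPOX
PPOX
FECH
HFE
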
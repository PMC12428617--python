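amino_acid,taste_class
glycine,sweet
L-alanine,sweet
L-serine,sweet
L-threonine,sweet
L-proline,sweet
L-glutamine,sweet
beta-alanine,sweet
L-lysine,sweet-bitter
L-valine,neutral
L-asparagine,neutral
L-cysteine,neutral
L-citrulline,neutral
4-aminobutyric acid,neutral
L-leucine,bitter
L-isoleucine,bitter
L-methionine,bitter
L-phenylalanine,bitter
L-tryptophan,bitter
L-tyrosine,bitter
L-arginine,bitter
L-histidine,bitter
L-ornithine,bitter
L-aspartic acid,umami
L-glutamic acid,umami
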
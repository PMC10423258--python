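# Cell-culture growth medium profile: 44 uptake-permitted metabolites.
# Transcribed from the composition of Ham's F-12 culture medium (amino acids,
# vitamins, and carbon sources) plus essential ions and nutrients supplied by
# serum supplements. One metabolite per line; '#' starts a comment.
alanine
arginine
asparagine
aspartate
cysteine
glutamate
glutamine
glycine
histidine
isoleucine
leucine
lysine
methionine
phenylalanine
proline
serine
threonine
tryptophan
tyrosine
valine
biotin
choline
folate
inositol
nicotinamide
pantothenate
pyridoxine
riboflavin
thiamin
vitamin B12
glucose
hypoxanthine
linoleate
lipoic acid
putrescine
pyruvate
thymidine
O2
Fe2+
Pi
sulfate
HCO3-
Na+
K+
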
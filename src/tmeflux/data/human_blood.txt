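# Human-blood nutrient profile: 64 uptake-permitted metabolites.
# Transcribed from the composition of human plasma-like medium (HPLM), which
# mirrors the small-molecule make-up of adult human plasma: amino acids,
# glucose, salts, vitamins, and the polar metabolites present at physiological
# concentration. One metabolite per line; '#' starts a comment.
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
glucose
O2
Na+
K+
Ca2+
Fe2+
Pi
sulfate
HCO3-
Cl-
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
lactate
pyruvate
citrate
acetate
acetoacetate
3-hydroxybutyrate
2-hydroxybutyrate
glycerol
carnitine
creatine
creatinine
citrulline
ornithine
taurine
urate
hypoxanthine
fructose
galactose
formate
malonate
acetone
hippurate
4-hydroxyproline
acetylglycine
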
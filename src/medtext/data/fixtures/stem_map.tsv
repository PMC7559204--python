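stem	category
arthrit	arthritis
arthr	arthritis
musculoskelet	joint/musculoskeletal problem
gastrit	gastrointestinal disease
ulc colit	gastrointestinal disease
asthm	asthma
diarrhe	autonomic symptoms
depress	depression and related disorders
diabet	diabetes
anxy	anxiety disorders
high blood press	hypertension
hypertend	hypertension
htn	hypertension
b/p	hypertension
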
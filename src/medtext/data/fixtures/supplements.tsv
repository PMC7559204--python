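vitamin c
vitamin b12
vit b12
vitamin d
vitamin e
multivitamin
fish oil
calcium
magnesium
iron
zinc
folic acid
melatonin
glucosamine
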
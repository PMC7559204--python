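acid
allergies
allergy
anxiety
arthritic
arthritis
asthma
asthmatic
blood
cholesterol
colitis
depression
diabetes
diarrhea
gastritis
headache
heart
high
hypertension
infection
inflammation
insomnia
joint
joints
migraine
mood
musculoskeletal
pain
pressure
reflux
sleep
thyroid
ulcer
ulcerative
vitamin
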
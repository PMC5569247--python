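abdomen
abscess
agony
anal
anxiety
appetite
arthritis
attack
belly
bladder
bleed
blood
bone
bowel
butt
colitis
constipation
cramp
damage
deficiency
depression
diabetes
diarrhea
digestion
disorder
exhausted
fever
fistula
flare
flu
gastro
grow
hurt
infection
inflamed
intestine
liver
mouth
muscle
nausea
pain
psoriasis
rectum
scar
severe
sleep
stress
suffer
symptom
tired
toilet
ulcer
vomit
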
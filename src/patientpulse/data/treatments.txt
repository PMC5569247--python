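adalimumab
aloe
antibiotic
asacol
azathioprine
budesonide
calcium
cannabis
capsule
certolizumab
cimzia
colectomy
colonoscopy
colostomy
diagnosis
diet
doctor
dose
drain
entocort
enzyme
fda
ferment
ginger
gp
health care
hospital
humira
ileostomy
imuran
infliximab
infusion
injection
kefir
marijuana
medication
medicine
mercaptopurine
methotrexate
morphine
mri
natural
nutrition
operation
oral
organic
paleo
pentasa
powder
prednisolone
prescribed
prescription
probiotic
rafton
remedy
remicade
resection
reversal
scd
solution
specialist
steroid
surgeon
surgery
test
therapy
transplant
treat
visit
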
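alcohol
bacteria
butter
cake
cell
chocolate
coffee
drink
eggs
food
gene
honey
lactose
map
meat
milk
pasta
smoke
sugar
tnf
virus
vitamin
wine
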
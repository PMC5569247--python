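afraid
angry
annoyed
anxious
awful
bad
depressed
disappointed
dreadful
fear
frightened
frustrated
hate
hopeless
horrible
miserable
nasty
negative
painful
poor
rough
sad
scared
sick
struggling
terrible
unbearable
uncomfortable
unhappy
upset
useless
weak
worried
worse
worst
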
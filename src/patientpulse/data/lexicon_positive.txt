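amazing
awesome
beneficial
better
blessed
brilliant
calm
comfortable
encouraging
excellent
fantastic
fine
glad
good
grateful
great
happy
healed
helpful
hopeful
improved
improvement
love
lucky
perfect
pleased
positive
recovered
relief
relieved
stronger
success
thankful
well
wonderful
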
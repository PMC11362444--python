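# Tentativeness word list (open approximation of an LIWC-2015-style category,
# written for this package). Stems end with '*'.
almost
ambigu*
any
anyhow
anytime
apparently
appear
appeared
appears
chance
chances
depend
depended
depending
depends
doubt
doubted
doubtful
doubts
guess
guessed
guesses
guessing
hardly
hesitant
hopeful
hopefully
hypothes*
indecis*
likely
luck
lucky
may
maybe
might
nearly
occasionally
perhaps
possibilit*
possible
possibly
presumably
probable
probably
seem
seemed
seeming
seemingly
seems
somehow
sometimes
somewhat
sort
sorta
suppose
supposed
supposes
supposing
tentative*
uncertain*
unclear
unlikely
unsure
vague*
wonder
wondered
wondering
wonders
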
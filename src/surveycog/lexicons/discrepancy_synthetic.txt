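# Discrepancy word list (open approximation of an LIWC-2015-style category,
# written for this package). Stems end with '*'.
could
could've
coulda
couldn't
expect
expectation*
expected
expecting
expects
hope
hoped
hopes
hoping
ideal
ideally
ideals
lack
lacked
lacking
lacks
mistake
mistaken
mistakes
must
mustn't
need
needed
needing
needs
ought
oughta
prefer
preferred
prefers
problem
problems
rather
regret
regrets
regretted
should
should've
shoulda
shouldn't
want
wanted
wanting
wants
wish
wished
wishes
wishing
would
would've
woulda
wouldn't
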
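# Negation word list (open approximation of an LIWC-2015-style category,
# written for this package). Stems end with '*'.
ain't
aren't
can't
cannot
couldn't
didn't
doesn't
don't
hadn't
hasn't
haven't
isn't
neither
never
no
nobody
none
nor
not
nothing
nowhere
shouldn't
wasn't
weren't
won't
wouldn't
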
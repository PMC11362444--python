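# Differentiation/exclusion word list (open approximation of an
# LIWC-2015-style category, written for this package). Stems end with '*'.
alternative
alternatives
although
apart
besides
but
contrast
contrasts
despite
differ
difference
differences
different
differently
differing
differs
distinct
distinction
either
else
elsewhere
except
exclude
excluded
excluding
exclusion
hasn't
instead
neither
or
other
others
otherwise
rather
though
unless
unlike
versus
whereas
whether
without
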
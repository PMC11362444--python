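# Conjunction word list (open approximation of an LIWC-2015-style category,
# written for this package). Stems end with '*'.
also
although
and
as
because
but
either
how
however
if
nor
once
or
since
so
then
though
unless
until
when
whenever
whereas
whether
while
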
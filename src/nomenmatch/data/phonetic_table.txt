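# Phonetic normalization table for scientific-name components.
# One rule per line: pattern<TAB>replacement
# Rules prefixed with "^" apply only at the start of the string and are
# tried once, in file order, before the unanchored rules.  Unanchored
# rules are applied repeatedly until the string stops changing.
# "ch" is handled in code (replaced by "c" only when not string-initial).
^mc	mac
^x	z
^ps	s
^pt	t
^ts	s
ae	e
oe	e
ph	f
th	t
sz	s
y	i
k	c
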
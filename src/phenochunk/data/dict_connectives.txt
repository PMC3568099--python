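# connective / prepositional tokens (unigram gazetteer)
at
in
of
on
to
with
within
without
from
by
for
into
between
under
over
near
along
across
through
during
as
than
versus
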
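# Small English stop-word list (function words only).
the
a
an
of
and
or
in
on
at
to
for
with
by
from
is
are
was
were
this
that
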
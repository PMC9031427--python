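# Stopwords consulted by the adjacent-word extension rules: a stopword is
# never prepended/appended to an entity. Small fixed English list, v1.
a
an
and
are
as
at
be
but
by
for
from
has
have
in
is
it
its
of
on
or
than
that
the
their
these
this
those
to
was
were
with
which
when
while
we
not
no
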
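# English function words removed from dictionary patterns before matching.
# One term per line; lines starting with '#' are ignored.
about
after
all
also
and
any
are
because
been
before
being
best
between
both
but
can
could
did
does
done
during
each
for
from
had
has
have
having
her
here
his
how
into
its
large
may
might
more
most
not
other
our
over
per
same
should
small
some
such
than
that
the
their
them
then
there
these
they
this
those
type
under
use
used
very
was
were
what
when
where
which
while
who
will
with
would
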
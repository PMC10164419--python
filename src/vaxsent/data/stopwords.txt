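# Default English stop-word list (one word per line, lowercase).
# Compact by design: function words only. Temporal prepositions such as
# "after"/"before" and ordinals are intentionally retained as content words,
# since vaccine chatter ("after first dose") carries signal in them.
a
an
the
and
or
but
nor
so
yet
if
then
than
that
this
these
those
i
me
my
mine
we
us
our
ours
you
your
yours
he
him
his
she
her
hers
it
its
they
them
their
theirs
who
whom
whose
which
what
where
when
why
how
am
is
are
was
were
be
been
being
have
has
had
having
do
does
did
doing
will
would
shall
should
can
could
may
might
must
of
in
on
at
to
for
with
from
by
as
into
onto
about
over
under
again
further
here
there
all
any
both
each
few
more
most
other
some
such
only
own
same
too
very
just
because
while
during
until
up
down
out
off
now
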
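# Default English stop-word list: articles, pronouns, prepositions,
# conjunctions, auxiliaries, common adverbs. One lowercase term per line.
a
about
above
after
again
against
all
also
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
did
do
does
doing
down
during
each
either
else
ever
every
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
however
i
if
in
into
is
it
its
itself
just
least
less
many
may
me
might
more
most
much
must
my
myself
neither
no
nor
not
now
of
off
on
once
only
onto
or
other
others
otherwise
our
ours
ourselves
out
over
own
per
rather
same
shall
she
should
since
so
some
such
than
that
the
their
theirs
them
themselves
then
there
therefore
these
they
this
those
through
thus
to
too
under
until
up
upon
us
very
was
we
were
what
when
where
whether
which
while
who
whom
whose
why
will
with
within
without
would
yet
you
your
yours
yourself
yourselves
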
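a
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
came
can
come
could
did
do
does
doing
done
down
during
each
either
few
for
from
further
get
got
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
like
may
me
might
more
most
much
must
my
myself
no
nor
not
now
of
off
on
once
one
only
onto
or
other
our
ours
ourselves
out
over
own
per
same
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
these
they
this
those
through
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
although
among
anyone
anything
around
away
cannot
else
ever
every
everyone
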
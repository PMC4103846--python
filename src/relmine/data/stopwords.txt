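a
about
above
after
again
against
all
also
although
am
among
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
may
me
might
more
most
must
my
myself
nor
of
off
on
once
only
or
other
our
ours
ourselves
out
over
own
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
why
will
with
within
without
would
you
your
yours
yourself
yourselves
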
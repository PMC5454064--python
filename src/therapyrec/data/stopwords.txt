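i
me
my
mine
we
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
they
them
their
it
its
a
an
the
and
or
but
if
then
because
as
of
to
in
on
at
by
for
with
about
from
into
over
under
again
so
very
really
just
too
also
here
there
when
where
how
what
which
who
this
that
these
those
is
am
are
was
were
be
been
being
have
has
had
do
does
did
doing
will
would
can
could
should
feel
feeling
felt
new
old
some
any
all
more
most
not
no
never
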
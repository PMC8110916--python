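a
about
afternoon
again
almost
also
always
am
an
and
another
any
are
as
ask
asked
asking
asks
at
ate
away
bad
be
beautiful
because
been
behind
being
beside
big
biscuit
boy
busy
but
by
cabinet
came
can
care
cared
careless
cares
caring
child
children
climb
climbed
climbing
climbs
close
closed
closes
closing
cloth
come
comes
coming
commotion
cookie
cookies
could
cup
cupboard
curtain
curtains
daughter
day
did
dim
dish
dishcloth
dishes
distracted
do
does
doing
done
door
down
dried
dries
drip
dripped
dripping
drips
dry
drying
each
eat
eating
eats
eight
empty
every
everything
eye
fall
fallen
falling
falls
father
feet
fell
finish
finished
finishes
finishing
five
floor
foot
for
four
from
full
fun
garden
gave
get
gets
getting
girl
give
gives
giving
glass
glasses
go
goes
going
gone
good
got
gotten
grab
grabbed
grabbing
grabs
had
hand
happen
happened
happening
happens
happy
has
have
having
he
head
held
help
helped
helping
helps
her
here
herself
high
him
himself
his
hm
hold
holding
holds
home
hot
house
i
if
in
indifferent
inside
into
is
it
its
itself
jar
just
keep
keeping
keeps
kept
kitchen
knew
know
knowing
knows
lady
laugh
laughed
laughing
laughs
let
lets
letting
like
liked
likes
liking
little
look
looked
looking
looks
lot
low
mad
made
make
makes
making
man
many
may
maybe
me
men
messy
might
moment
more
morning
most
mother
much
must
my
near
need
needed
needing
needs
never
nice
nine
no
nor
not
notice
noticed
notices
noticing
now
oblivious
odd
of
often
oh
old
on
one
open
or
other
our
out
outside
over
overflow
overflowed
overflowing
overflows
perhaps
person
picture
plate
play
played
playing
plays
point
pointed
pointing
points
pour
poured
pouring
pours
problem
put
puts
putting
quiet
quite
ran
reach
reached
reaches
reaching
ready
really
right
room
run
running
runs
sad
said
saw
say
saying
says
see
seeing
seem
seemed
seems
seen
sees
seven
shall
she
shelf
should
side
sink
sister
situation
six
slip
slipped
slipping
slips
small
smile
smiled
smiles
smiling
so
some
something
son
soon
spill
spilled
spilling
spills
stand
standing
stands
start
started
starting
starts
steal
stealing
steals
still
stole
stolen
stood
stool
summer
sunny
take
taken
takes
taking
tall
tell
telling
tells
ten
that
the
their
them
themselves
then
there
these
they
thing
things
think
thinking
thinks
this
those
thought
three
three-legged
through
time
tip
tipped
tipping
tips
to
told
too
took
towel
tried
tries
trouble
try
trying
turn
turned
turning
turns
two
uh
um
unconcerned
under
unsteady
up
us
use
used
uses
using
very
wall
want
wanted
wants
was
wash
washed
washes
washing
watch
watched
watches
watching
water
way
we
weather
well
went
were
wet
while
whole
will
window
wipe
wiped
wipes
wiping
with
wobble
wobbled
wobbles
wobbling
woman
women
wonderful
work
worked
working
works
would
yard
yeah
yes
yet
you
young
your
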
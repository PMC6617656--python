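the
of
and
a
to
in
is
was
he
for
on
are
as
with
his
they
at
be
this
have
from
or
one
had
by
word
but
not
what
all
were
we
when
your
can
said
there
use
an
each
which
she
do
how
their
if
will
up
other
about
out
many
then
them
these
so
some
her
would
make
like
him
into
time
has
look
two
more
write
go
see
number
no
way
could
people
my
than
first
water
been
call
who
oil
its
now
find
long
down
day
did
get
come
made
may
part
over
new
sound
take
only
little
work
know
place
year
live
me
back
give
most
very
after
thing
our
just
name
good
sentence
man
think
say
great
where
help
through
much
before
line
right
too
mean
old
any
same
tell
boy
follow
came
want
show
also
around
form
three
small
set
put
end
does
another
well
large
must
big
even
such
because
turn
here
why
ask
went
men
read
need
land
different
home
us
move
try
kind
hand
picture
again
change
off
play
spell
air
away
animal
house
point
page
letter
mother
answer
found
study
still
learn
should
world
high
every
near
add
food
between
own
below
country
plant
last
school
father
keep
tree
never
start
city
earth
eye
light
thought
head
under
story
saw
left
few
while
along
might
close
something
seem
next
hard
open
example
begin
life
always
those
both
paper
together
got
group
often
run
important
until
children
side
feet
car
mile
walk
white
sea
began
grow
took
river
four
carry
state
once
book
hear
stop
without
second
later
miss
idea
enough
eat
face
watch
far
really
almost
let
above
girl
sometimes
mountain
cut
young
talk
soon
list
song
being
leave
family
night
day
week
month
person
patient
suffered
suffering
since
became
become
taken
brought
given
told
felt
fell
ill
illness
sick
sickness
severe
sudden
suddenly
gradually
slowly
quickly
condition
problem
history
several
days
weeks
months
years
morning
evening
passed
away
happened
complained
complaint
symptoms
started
stopped
continued
worse
better
improved
recovered
unable
able
refused
returned
village
local
private
government
district
road
vehicle
driver
train
bus
truck
motorcycle
bicycle
tractor
field
farm
river
well
pond
house
kitchen
fire
fall
falling
fallen
slipped
struck
hit
knocked
during
immediately
finally
eventually
despite
advised
referred
tested
examined
diagnosed
reported
declared
consulted
visited
shifted
rushed
taken
brought
care
nursing
health
centre
center
primary
check
checkup
report
result
positive
negative
normal
abnormal
serious
critical
stable
unstable
conscious
semiconscious
drowsy
restless
shivering
trembling
sweating
pale
dull
dry
wet
hot
warm
cool
high
low
mild
moderate
heavy
light
sharp
constant
intermittent
frequent
occasional
daily
whole
half
quarter
full
empty
closed
opened
water
milk
rice
food
drink
eaten
drunk
swallowed
spat
yesterday
today
tomorrow
afternoon
midnight
noon
dawn
dusk
hour
hours
minute
minutes
moment
period
duration
onset
course
stage
early
late
final
terminal
old
elderly
aged
adult
child
baby
son
daughter
wife
husband
brother
sister
uncle
aunt
grandfather
grandmother
neighbour
neighbor
friend
relative
member
deceased
subject
respondent
interview
narrative
account
statement
according
says
said
stated
mentioned
noticed
observed
seen
heard
found
discovered
body
dead
alive
living
survived
expired
breathed
breath
last
lastly
peacefully
quietly
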
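# Default sentence-cleaning stop set: most common English verbs and their
# conjugations, common adjectives/adverbs, articles and number words.
# Deliberately excluded: kinship words and their modifiers (great, half,
# step, maternal, paternal), partner terms, pronouns, conjunctions,
# prepositions, negation cues (no/not/denies/without/never) and
# living-status phrases (alive, well, healthy, dead, deceased, died,
# living, passed, away, stillborn), which downstream rules rely on.
a
an
the
this
that
these
those
be
am
is
are
was
were
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
done
say
says
said
saying
get
gets
got
gotten
getting
make
makes
made
making
go
goes
went
gone
going
know
knows
knew
known
knowing
take
takes
took
taken
taking
see
sees
saw
seen
seeing
come
comes
came
coming
think
thinks
thought
thinking
look
looks
looked
looking
want
wants
wanted
wanting
give
gives
gave
given
giving
use
uses
used
using
find
finds
found
finding
tell
tells
told
telling
ask
asks
asked
asking
work
works
worked
working
seem
seems
seemed
seeming
feel
feels
felt
feeling
try
tries
tried
trying
leave
leaves
left
leaving
call
calls
called
calling
keep
keeps
kept
keeping
begin
begins
began
begun
show
shows
showed
shown
hear
hears
heard
play
plays
played
run
runs
ran
move
moves
moved
like
likes
liked
believe
believes
believed
bring
brings
brought
happen
happens
happened
write
writes
wrote
written
sit
sits
sat
stand
stands
stood
lose
loses
lost
pay
pays
paid
meet
meets
met
include
includes
included
including
continue
continues
continued
set
sets
learn
learns
learned
change
changes
changed
lead
leads
led
understand
understands
understood
watch
watched
stop
stops
stopped
speak
speaks
spoke
spoken
spend
spends
spent
grow
grows
grew
grown
open
opened
walk
walks
walked
win
wins
won
offer
offers
offered
remember
remembers
remembered
appear
appears
appeared
buy
buys
bought
wait
waits
waited
serve
serves
served
send
sends
sent
expect
expects
expected
build
builds
built
stay
stays
stayed
fall
fell
fallen
cut
cuts
reach
reaches
reached
remain
remains
remained
suggest
suggests
suggested
report
reports
reported
reporting
reportedly
note
notes
noted
state
states
stated
describe
describes
described
present
presents
presented
presenting
visit
visits
visited
suffer
suffers
suffered
suffering
undergo
undergoes
underwent
undergone
receive
receives
received
complain
complains
complained
admit
admits
admitted
follow
follows
followed
develop
develops
developed
diagnose
diagnoses
diagnosed
treat
treats
treated
examine
examines
examined
experience
experiences
experienced
require
requires
required
consider
considers
considered
indicate
indicates
indicated
reveal
reveals
revealed
mention
mentions
mentioned
good
nice
new
old
young
little
big
small
large
long
short
high
low
early
late
recent
recently
several
many
few
much
more
most
other
another
same
own
certain
various
numerous
multiple
significant
total
current
currently
previous
previously
approximately
about
also
now
then
still
very
quite
really
often
sometimes
usually
always
again
ago
age
aged
year
years
month
months
week
weeks
day
days
time
times
zero
one
two
three
four
five
six
seven
eight
nine
ten
eleven
twelve
twenty
thirty
forty
fifty
sixty
seventy
eighty
ninety
hundred
both
all
each
every
some
any
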
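# Synthetic familiar-word list in the style of the Dale-Chall list of words
# reliably understood by fourth-grade readers. This is an open approximation
# written for this package (the canonical list is not redistributed here);
# users may supply their own list. One word per line; '#' lines are comments.
a
able
about
above
accept
across
act
add
afraid
after
afternoon
again
against
age
ago
agree
ahead
air
all
almost
alone
along
already
also
always
am
among
an
and
anger
angry
animal
another
answer
any
anybody
anyone
anything
anywhere
apart
appear
apple
are
arm
around
arrive
art
as
ask
asleep
at
ate
attention
aunt
away
baby
back
bad
bag
ball
bank
base
basket
be
bean
bear
beat
beautiful
became
because
become
bed
been
before
began
begin
behind
being
believe
bell
belong
below
beside
besides
best
better
between
big
bill
bird
birthday
bit
black
block
blood
blow
blue
board
boat
body
bone
book
born
borrow
both
bother
bottle
bottom
bought
box
boy
branch
brave
bread
break
breakfast
breath
bridge
bright
bring
brother
brought
brown
build
burn
bus
busy
but
buy
by
cake
call
came
can
cannot
cap
car
card
care
careful
carry
case
cat
catch
caught
cause
cent
center
certain
certainly
chair
chance
change
chase
cheap
check
cheek
cheer
chicken
chief
child
children
choose
church
circle
city
class
clean
clear
climb
clock
close
cloth
clothes
cloud
coat
cold
color
come
comfort
coming
company
cook
cool
corn
corner
cost
could
count
country
course
cover
cow
crop
cross
crowd
cry
cup
cut
dad
daily
dance
dark
daughter
day
dead
deal
dear
decide
deep
den
desk
did
die
different
dig
dinner
direction
dirty
dish
do
doctor
does
dog
dollar
done
door
double
down
draw
dream
dress
drink
drive
drop
dry
duck
during
dust
duty
each
ear
early
earn
earth
east
easy
eat
edge
egg
eight
either
eleven
else
empty
end
enemy
enjoy
enough
enter
even
evening
ever
every
everybody
everyone
everything
everywhere
exact
except
excuse
expect
explain
extra
eye
face
fact
fair
fall
family
famous
far
farm
fast
fat
father
fault
favor
fear
feed
feel
feet
fell
fellow
felt
fence
few
field
fight
fill
find
fine
finger
finish
fire
first
fish
fit
five
fix
flag
flat
floor
flower
fly
follow
food
foot
for
forget
forgot
form
found
four
free
fresh
friend
friendly
from
front
fruit
full
fun
funny
future
game
garden
gate
gave
general
gentle
get
gift
girl
give
glad
glass
go
goes
going
gold
gone
good
got
grade
grand
grass
gray
great
green
grew
ground
group
grow
guess
had
hair
half
hand
handle
hang
happen
happy
hard
hardly
has
hat
hate
have
he
head
health
hear
heard
heart
heat
heavy
held
hello
help
her
here
hers
herself
hide
high
hill
him
himself
his
hit
hold
hole
holiday
home
honest
hope
horse
hot
hour
house
how
however
hundred
hungry
hunt
hurry
hurt
husband
i
ice
idea
if
ill
important
in
indeed
inside
instead
into
is
it
its
itself
job
join
joke
joy
jump
just
keep
kept
kill
kind
king
kiss
kitchen
knee
knew
know
known
lady
laid
lake
land
large
last
late
laugh
lay
lazy
lead
learn
least
leave
left
leg
lend
less
lesson
let
letter
lie
life
lift
light
like
likely
line
lion
lip
list
listen
little
live
load
long
look
lose
lost
lot
loud
love
low
luck
lucky
lunch
made
mail
main
make
man
many
map
mark
market
marry
master
matter
may
maybe
me
meal
mean
meant
measure
meat
meet
member
men
mend
middle
might
mile
milk
mind
mine
minute
miss
mistake
moment
money
month
moon
more
morning
most
mother
mountain
mouth
move
much
music
must
my
myself
name
near
nearly
neck
need
neighbor
neither
nest
never
new
news
next
nice
night
nine
no
nobody
noise
none
noon
nor
north
nose
not
note
nothing
now
nowhere
number
nurse
of
off
offer
office
often
oh
old
on
once
one
only
open
or
orange
order
other
others
otherwise
ought
our
ours
ourselves
out
outside
over
own
page
paid
pain
paint
pair
pan
paper
parent
park
part
party
pass
past
pay
peace
pen
pencil
penny
people
perhaps
person
pick
picture
piece
pig
place
plan
plant
play
pleasant
please
plenty
pocket
point
poor
pop
possible
post
pot
pound
pour
power
prepare
present
pretty
price
prize
probably
problem
promise
proud
prove
pull
purpose
push
put
queen
question
quick
quiet
quite
rabbit
race
rain
raise
ran
rather
reach
read
ready
real
really
reason
red
remember
rest
return
rich
ride
right
ring
rise
river
road
rock
roll
roof
room
rope
rose
round
row
rub
rule
run
sad
safe
said
sail
salt
same
sand
sat
save
saw
say
school
sea
season
seat
second
see
seed
seem
seen
self
sell
send
sense
sent
serve
set
settle
seven
several
shake
shall
shape
share
she
sheep
shine
ship
shirt
shoe
shop
short
should
shoulder
shout
show
shut
sick
side
sight
sign
silver
simple
since
sing
sister
sit
six
size
skin
sky
sleep
slow
small
smart
smell
smile
snow
so
soft
sold
some
somebody
somehow
someone
something
sometime
sometimes
somewhere
son
song
soon
sorry
sort
sound
south
space
speak
special
spend
spent
spoke
spot
spread
spring
square
stand
star
start
state
station
stay
step
stick
still
stone
stood
stop
store
storm
story
straight
strange
street
strong
such
sudden
sugar
summer
sun
supper
suppose
sure
surprise
sweet
swim
table
tail
take
talk
tall
taste
teach
teacher
team
tear
teeth
tell
ten
tent
than
thank
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
thick
thin
thing
think
third
this
those
though
thought
thousand
three
threw
through
throw
tie
till
time
tiny
tired
to
today
together
told
tomorrow
tonight
too
took
top
touch
toward
town
toy
train
travel
treat
tree
tried
trip
trouble
true
trust
try
turn
twelve
twenty
twice
two
uncle
under
understand
unless
until
up
upon
us
use
useful
usual
very
visit
voice
wait
wake
walk
wall
want
war
warm
was
wash
waste
watch
water
way
we
wear
weather
week
welcome
well
went
were
west
wet
what
wheel
when
where
whether
which
while
white
who
whole
whom
whose
why
wide
wife
wild
will
win
wind
window
winter
wise
wish
with
within
without
woke
woman
women
wonder
wonderful
wood
word
wore
work
world
worry
worse
worst
worth
would
write
wrong
wrote
yard
year
yellow
yes
yesterday
yet
you
young
your
yours
yourself
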
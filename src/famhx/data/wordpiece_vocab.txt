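# Bundled demonstration wordpiece vocabulary (## marks continuation
# pieces).  Big enough to reproduce realistic subword splitting of
# disease terms (carcinoma -> car ##cin ##oma) while keeping common
# words whole (mother -> mother); pretrained vocabularies plug in via
# the same file format.
[UNK]
a
b
c
d
e
f
g
h
i
j
k
l
m
n
o
p
q
r
s
t
u
v
w
x
y
z
##a
##b
##c
##d
##e
##f
##g
##h
##i
##j
##k
##l
##m
##n
##o
##p
##q
##r
##s
##t
##u
##v
##w
##x
##y
##z
0
1
2
3
4
5
6
7
8
9
##0
##1
##2
##3
##4
##5
##6
##7
##8
##9
.
,
;
:
!
?
(
)
'
"
-
/
acute
alive
also
am
an
and
anemia
anxiety
are
arthritis
as
asthma
at
attack
aunt
aunts
away
be
been
blood
bone
both
breast
brother
but
by
cancer
cell
child
children
cholesterol
chronic
cirrhosis
colon
cousin
cousins
daughter
daughters
dead
deceased
dementia
depression
diabetes
did
died
disease
disorder
do
does
doing
dr
eczema
epilepsy
evidence
failure
father
for
from
general
good
gout
grandfather
grandmother
grandparent
grandparents
great
had
half
has
have
he
health
healthy
heart
hepatitis
her
high
his
history
husband
hypertension
in
is
it
its
kidney
liver
living
loss
lung
lupus
maternal
mellitus
migraine
migraines
mother
mr
mrs
ms
nephew
nephews
niece
nieces
no
not
obesity
of
on
one
or
otherwise
parent
parents
partner
passed
paternal
patient
patients
pressure
problems
psoriasis
report
reports
seizures
several
she
sibling
siblings
sickle
sister
skin
son
sons
spouse
stillborn
stroke
syndrome
that
the
their
them
they
this
three
thyroid
to
two
type
uncle
uncles
was
well
were
which
who
wife
with
without
car
##cin
##oma
leu
##kem
##ia
mel
##an
lym
##pho
##ma
cys
##tic
fibro
##sis
osteo
##porosis
hemo
##philia
thala
##ssemia
glau
##coma
cata
##ract
##racts
neur
##opathy
scoli
##osis
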
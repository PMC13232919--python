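%
1	article
2	prep
3	ppron
4	ipron
5	auxverb
6	conj
7	adverb
8	negate
9	posemo
10	negemo
11	sad
12	anx
13	social
14	informal
%
a	1
an	1
the	1
in	2
on	2
at	2
of	2
to	2
from	2
with	2
about	2
over	2
under	2
between	2
through	2
i	3
me	3
my	3
mine	3
you	3
your	3
he	3
she	3
him	3
her	3
we	3
us	3
our	3
they	3
them	3
their	3
it	4
its	4
this	4
that	4
these	4
those	4
something	4
anything	4
nothing	4	8
somebody	4	13
anyone	4
everyone	4	13
am	5
is	5
are	5
was	5
were	5
be	5
been	5
being	5
have	5
has	5
had	5
do	5
does	5
did	5
will	5
would	5
can	5
could	5
shall	5
should	5
may	5
might	5
must	5
and	6
but	6
or	6
because	6
so	6
although	6
while	6
whereas	6
however	6	7
very	7
really	7
quite	7
rather	7
always	7
never	7	8
often	7
sometimes	7
maybe	7
perhaps	7
again	7
still	7
just	7
no	8
not	8
none	8
cannot	8
can't	8	14
don't	8	14
won't	8	14
isn't	8	14
didn't	8	14
happy	9
happ*	9
joy*	9
glad	9
hope*	9
love*	9	13
kind	9
warm	9
proud	9
grateful	9
support*	9	13
care	9	13
caring	9	13
sad	10	11
sadness	10	11
unhappy	10	11
cry*	10	11
grief	10	11
miserable	10	11
hurt*	10
pain*	10
alone	10	11
lonely	10	11
worthless	10
hate*	10
angry	10
fear*	10	12
afraid	10	12
worry	10	12
worried	10	12
anxious	10	12
nervous	10	12
panic	10	12
friend*	13
family	13
mother	13
father	13
brother	13
sister	13
neighbor	13
talk*	13
listen*	13
together	13
community	13
lol	14
omg	14
gonna	14
wanna	14
gotta	14
kinda	14
yeah	14
nah	14	8
btw	14
idk	14
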
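# synthetic clinical-lexicon excerpt: word<TAB>lemma<TAB>pos
# (concise tag set: noun/adj/verb/adv/prep/conj/det/num)
# Coverage is deliberately partial; out-of-list tokens are reported absent.
the	the	det
a	a	det
an	an	det
and	and	conj
or	or	conj
of	of	prep
in	in	prep
at	at	prep
with	with	prep
is	be	verb
are	be	verb
was	be	verb
were	be	verb
shows	show	verb
showing	show	verb
show	show	verb
appear	appear	verb
appears	appear	verb
demonstrates	demonstrate	verb
demonstrate	demonstrate	verb
reveals	reveal	verb
note	note	verb
noted	note	verb
seen	see	verb
bone	bone	noun
bones	bone	noun
rib	rib	noun
ribs	rib	noun
thorax	thorax	noun
femur	femur	noun
tibia	tibia	noun
radius	radius	noun
ulna	ulna	noun
spine	spine	noun
vertebra	vertebra	noun
vertebrae	vertebra	noun
hand	hand	noun
hands	hand	noun
foot	foot	noun
feet	foot	noun
thumb	thumb	noun
finger	finger	noun
fingers	finger	noun
skull	skull	noun
pelvis	pelvis	noun
head	head	noun
heads	head	noun
joint	joint	noun
joints	joint	noun
patient	patient	noun
patients	patient	noun
radiograph	radiograph	noun
radiographs	radiograph	noun
film	film	noun
image	image	noun
figure	figure	noun
view	view	noun
age	age	noun
years	year	noun
short	short	adj
long	long	adj
broad	broad	adj
wide	wide	adj
narrow	narrow	adj
small	small	adj
large	large	adj
thick	thick	adj
thin	thin	adj
flat	flat	adj
irregular	irregular	adj
abnormal	abnormal	adj
normal	normal	adj
left	left	adj
right	right	adj
bilateral	bilateral	adj
central	central	adj
proximal	proximal	adj
distal	distal	adj
anterior	anterior	adj
posterior	posterior	adj
medial	medial	adj
lateral	lateral	adj
mild	mild	adj
severe	severe	adj
subtle	subtle	adv
markedly	markedly	adv
mildly	mildly	adv
slightly	slightly	adv
one	one	num
two	two	num
three	three	num
four	four	num
five	five	num
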
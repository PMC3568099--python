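# quality gazetteer excerpt (PATO-style unigram terms)
short
shortened
shortening
small
long
elongated
elongation
broad
broadened
wide
widened
widening
narrow
narrowed
narrowing
flat
flattened
flattening
square
squared
squaring
round
rounded
irregular
irregularity
hypoplastic
hypoplasia
aplastic
aplasia
dysplastic
dysplasia
hyperplastic
bowed
bowing
curved
curvature
angulated
angulation
thick
thickened
thickening
thin
thinned
thinning
large
enlarged
enlargement
cupped
cupping
fragmented
fragmentation
sclerotic
sclerosis
osteopenic
osteopenia
lucent
lucency
dense
density
bell-shaped
cone-shaped
wedge-shaped
spade-like
trident
hitchhiker
bone-in-bone
absent
absence
missing
delayed
advanced
accelerated
abnormal
abnormality
deformed
deformity
dislocated
dislocation
subluxation
fusion
fused
segmentation
ossification
ossified
unossified
mineralization
demineralized
overtubulated
undertubulation
undermodelled
gracile
slender
stippled
stippling
beaked
beaking
scalloped
scalloping
platyspondyly
brachydactyly
arachnodactyly
clinodactyly
polydactyly
syndactyly
campomelia
coxa
vara
valga
genu
valgum
varum
kyphosis
scoliosis
lordosis
kyphoscoliosis
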
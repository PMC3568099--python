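# anatomy gazetteer excerpt (FMA-style unigram terms; user-supplied full
# term dumps can be loaded the same way)
thorax
rib
ribs
ribcage
chest
femur
femora
femoral
tibia
tibiae
fibula
fibulae
humerus
humeri
humeral
radius
radii
ulna
ulnae
clavicle
clavicles
clavicular
scapula
scapulae
vertebra
vertebrae
vertebral
metacarpal
metacarpals
metatarsal
metatarsals
phalanx
phalanges
phalangeal
skull
cranium
calvaria
mandible
mandibular
maxilla
pelvis
pelvic
ilium
iliac
ischium
ischial
pubis
pubic
spine
spinal
sternum
sternal
patella
patellae
carpal
carpals
carpus
tarsal
tarsals
tarsus
epiphysis
epiphyses
epiphyseal
metaphysis
metaphyses
metaphyseal
diaphysis
diaphyses
diaphyseal
bone
bones
thumb
thumbs
finger
fingers
toe
toes
hand
hands
foot
feet
hip
hips
knee
knees
elbow
elbows
shoulder
shoulders
wrist
wrists
ankle
ankles
head
heads
neck
trunk
limb
limbs
joint
joints
cartilage
acetabulum
acetabula
acetabular
odontoid
sacrum
coccyx
symphysis
cortex
cortices
trochanter
condyle
condyles
malleolus
olecranon
glenoid
orbit
orbits
frontal
parietal
occipital
temporal
sella
sutures
fontanelle
fontanelles
digit
digits
hallux
pollex
capitulum
trochlea
talus
calcaneus
navicular
cuboid
scaphoid
lunate
hamate
ischia
pedicle
pedicles
lamina
laminae
endplate
endplates
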
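# anatomical coordinates and laterality (unigram gazetteer)
central
left
right
bilateral
bilaterally
unilateral
proximal
proximally
distal
distally
anterior
posterior
medial
lateral
superior
inferior
upper
lower
radial
ulnar
tibial
fibular
dorsal
ventral
palmar
plantar
cranial
caudal
cervical
thoracic
lumbar
sacral
axial
appendicular
midline
peripheral
terminal
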
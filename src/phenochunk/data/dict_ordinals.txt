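# ordinal expressions (unigram gazetteer)
1st
2nd
3rd
4th
5th
6th
7th
8th
9th
10th
11th
12th
13th
14th
15th
20th
first
second
third
fourth
fifth
sixth
seventh
eighth
ninth
tenth
eleventh
twelfth
i
ii
iii
iv
v
vi
vii
viii
ix
x
xi
xii
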
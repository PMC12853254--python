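phoneme	voicing	manner	place	roundness	frontback
p	unvoiced	occlusive	labial	unrounded	.
b	voiced	occlusive	labial	unrounded	.
t	unvoiced	occlusive	coronal	unrounded	.
d	voiced	occlusive	coronal	unrounded	.
k	unvoiced	occlusive	velar	unrounded	.
g	voiced	occlusive	velar	unrounded	.
f	unvoiced	fricative	labial	unrounded	.
v	voiced	fricative	labial	unrounded	.
s	unvoiced	fricative	coronal	unrounded	.
z	voiced	fricative	coronal	unrounded	.
S	unvoiced	fricative	coronal	unrounded	.
Z	voiced	fricative	coronal	unrounded	.
x	unvoiced	fricative	velar	unrounded	.
G	voiced	fricative	velar	unrounded	.
h	unvoiced	fricative	glottal	unrounded	.
T	unvoiced	fricative	dental	unrounded	.
D	voiced	fricative	dental	unrounded	.
m	voiced	nasal	labial	unrounded	.
n	voiced	nasal	coronal	unrounded	.
N	voiced	nasal	velar	unrounded	.
J	voiced	nasal	coronal	unrounded	.
l	voiced	approximant	coronal	unrounded	.
r	voiced	approximant	coronal	unrounded	.
w	voiced	approximant	labial	rounded	.
j	voiced	approximant	coronal	unrounded	.
I	voiced	short_vowel	high	unrounded	front
E	voiced	short_vowel	mid	unrounded	front
A	voiced	short_vowel	low	unrounded	back
O	voiced	short_vowel	mid	rounded	back
Y	voiced	short_vowel	high	rounded	front
@	voiced	short_vowel	mid	unrounded	central
i	voiced	long_vowel	high	unrounded	front
y	voiced	long_vowel	high	rounded	front
u	voiced	long_vowel	high	rounded	back
e	voiced	long_vowel	mid	unrounded	front
2	voiced	long_vowel	mid	rounded	front
o	voiced	long_vowel	mid	rounded	back
a	voiced	long_vowel	low	unrounded	central
Ei	voiced	long_vowel	mid	unrounded	front
9y	voiced	long_vowel	mid	rounded	front
Au	voiced	long_vowel	mid	rounded	back
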
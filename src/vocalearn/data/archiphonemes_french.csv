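phoneme,archiphoneme
p,|pb|
b,|pb|
t,|td|
d,|td|
k,|kg|
g,|kg|
f,|fv|
v,|fv|
s,|sz|
z,|sz|
S,|SZ|
Z,|SZ|
h,|h|
m,|m|
n,|n|
N,|n|
J,|J|
w,|w|
i,|ie|
e,|ie|
E,|ie|
ji,|ie|
je,|ie|
jE,|ie|
ri,|ie|
re,|ie|
rE,|ie|
li,|ie|
le,|ie|
lE,|ie|
a,|A|
a~,|A|
A,|A|
ja,|A|
ja~,|A|
jA,|A|
ra,|A|
ra~,|A|
rA,|A|
la,|A|
la~,|A|
lA,|A|
o,|O|
o~,|O|
O,|O|
jo,|O|
jo~,|O|
jO,|O|
ro,|O|
ro~,|O|
rO,|O|
lo,|O|
lo~,|O|
lO,|O|
u,|UV|
y,|UV|
ju,|UV|
jy,|UV|
ru,|UV|
ry,|UV|
lu,|UV|
ly,|UV|
e~,|&|
2,|&|
9,|&|
9~,|&|
@,|&|
je~,|&|
j2,|&|
j9,|&|
j9~,|&|
j@,|&|
re~,|&|
r2,|&|
r9,|&|
r9~,|&|
r@,|&|
le~,|&|
l2,|&|
l9,|&|
l9~,|&|
l@,|&|
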
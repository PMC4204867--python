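phoneme,archiphoneme
p,|pb|
b,|pb|
t,|td|
d,|td|
k,|kg|
g,|kg|
C,|kg|
x,|kg|
ts,|tSdZ|
tS,|tSdZ|
dZ,|tSdZ|
?,|?|
pf,|fv|
f,|fv|
v,|fv|
T,|TD|
D,|TD|
s,|sz|
z,|sz|
S,|SZ|
Z,|SZ|
h,|h|
m,|m|
n,|n|
N,|n|
R,|R|
l,|l|
j,|j|
I,|ie|
E,|ie|
i:,|ie|
e:,|ie|
E:,|ie|
jI,|ie|
jE,|ie|
ji:,|ie|
je:,|ie|
jE:,|ie|
rI,|ie|
rE,|ie|
ri:,|ie|
re:,|ie|
rE:,|ie|
lI,|ie|
lE,|ie|
li:,|ie|
le:,|ie|
lE:,|ie|
a,|A|
a:,|A|
aI,|A|
aU,|A|
ja,|A|
ja:,|A|
jaI,|A|
jaU,|A|
ra,|A|
ra:,|A|
raI,|A|
raU,|A|
la,|A|
la:,|A|
laI,|A|
laU,|A|
O,|O|
o:,|O|
OY,|O|
jO,|O|
jo:,|O|
jOY,|O|
rO,|O|
ro:,|O|
rOY,|O|
lO,|O|
lo:,|O|
lOY,|O|
Y,|UV|
U,|UV|
u:,|UV|
y:,|UV|
jY,|UV|
jU,|UV|
ju:,|UV|
jy:,|UV|
rY,|UV|
rU,|UV|
ru:,|UV|
ry:,|UV|
lY,|UV|
lU,|UV|
lu:,|UV|
ly:,|UV|
9,|&|
2:,|&|
@,|&|
6,|&|
j9,|&|
j2:,|&|
j@,|&|
j6,|&|
r9,|&|
r2:,|&|
r@,|&|
r6,|&|
l9,|&|
l2:,|&|
l@,|&|
l6,|&|
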
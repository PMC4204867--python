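phoneme,archiphoneme
p,|pb|
b,|pb|
t,|td|
d,|td|
k,|kg|
g,|kg|
tS,|tSdZ|
dZ,|tSdZ|
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
r,|r|
l,|l|
j,|j|
w,|w|
I,|ie|
i,|ie|
e,|ie|
E,|ie|
i:,|ie|
eI,|ie|
I@,|ie|
e@,|ie|
jI,|ie|
ji,|ie|
je,|ie|
jE,|ie|
ji:,|ie|
jeI,|ie|
jI@,|ie|
je@,|ie|
rI,|ie|
ri,|ie|
re,|ie|
rE,|ie|
ri:,|ie|
reI,|ie|
rI@,|ie|
re@,|ie|
lI,|ie|
li,|ie|
le,|ie|
lE,|ie|
li:,|ie|
leI,|ie|
lI@,|ie|
le@,|ie|
{,|A|
A:,|A|
A,|A|
aI,|A|
aU,|A|
j{,|A|
jA:,|A|
jA,|A|
jaI,|A|
jaU,|A|
r{,|A|
rA:,|A|
rA,|A|
raI,|A|
raU,|A|
l{,|A|
lA:,|A|
lA,|A|
laI,|A|
laU,|A|
Q,|O|
O,|O|
O:,|O|
OI,|O|
jQ,|O|
jO,|O|
jO:,|O|
jOI,|O|
rQ,|O|
rO,|O|
rO:,|O|
rOI,|O|
lQ,|O|
lO,|O|
lO:,|O|
lOI,|O|
V,|UV|
U,|UV|
u,|UV|
u:,|UV|
U@,|UV|
jV,|UV|
jU,|UV|
ju,|UV|
ju:,|UV|
jU@,|UV|
rV,|UV|
rU,|UV|
ru,|UV|
ru:,|UV|
rU@,|UV|
lV,|UV|
lU,|UV|
lu,|UV|
lu:,|UV|
lU@,|UV|
3:,|&|
3`,|&|
@U,|&|
@,|&|
@`,|&|
j3:,|&|
j3`,|&|
j@U,|&|
j@,|&|
j@`,|&|
r3:,|&|
r3`,|&|
r@U,|&|
r@,|&|
r@`,|&|
l3:,|&|
l3`,|&|
l@U,|&|
l@,|&|
l@`,|&|
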
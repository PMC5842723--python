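# BLOSUM30 amino-acid substitution matrix (1/5 bit units);
# canonical NCBI scoring table, 20 standard residues plus B/Z/X.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  B  Z  X
A   4  -1   0   0  -3   1   0   0  -2   0  -1   0   1  -2  -1   1   1  -5  -4   1   0   0   0
R  -1   8  -2  -1  -2   3  -1  -2  -1  -3  -2   1   0  -1  -1  -1  -3   0   0  -1  -2   0  -1
N   0  -2   8   1  -1  -1  -1   0  -1   0  -2   0   0  -1  -3   0   1  -7  -4  -2   4  -1   0
D   0  -1   1   9  -3  -1   1  -1  -2  -4  -1   0  -3  -5  -1   0  -1  -4  -1  -2   5   0  -1
C  -3  -2  -1  -3  17  -2   1  -4  -5  -2   0  -3  -2  -3  -3  -2  -2  -2  -6  -2  -2   0  -2
Q   1   3  -1  -1  -2   8   2  -2   0  -2  -2   0  -1  -3   0  -1   0  -1  -1  -3  -1   4   0
E   0  -1  -1   1   1   2   6  -2   0  -3  -1   2  -1  -4   1   0  -2  -1  -2  -3   0   5  -1
G   0  -2   0  -1  -4  -2  -2   8  -3  -1  -2  -1  -2  -3  -1   0  -2   1  -3  -3   0  -2  -1
H  -2  -1  -1  -2  -5   0   0  -3  14  -2  -1  -2   2  -3   1  -1  -2  -5   0  -3  -2   0  -1
I   0  -3   0  -4  -2  -2  -3  -1  -2   6   2  -2   1   0  -3  -1   0  -3  -1   4  -2  -3   0
L  -1  -2  -2  -1   0  -2  -1  -2  -1   2   4  -2   2   2  -3  -2   0  -2   3   1  -1  -1   0
K   0   1   0   0  -3   0   2  -1  -2  -2  -2   4   2  -1   1   0  -1  -2  -1  -2   0   1   0
M   1   0   0  -3  -2  -1  -1  -2   2   1   2   2   6  -2  -4  -2   0  -3  -1   0  -2  -1   0
F  -2  -1  -1  -5  -3  -3  -4  -3  -3   0   2  -1  -2  10  -4  -1  -2   1   3   1  -3  -4  -1
P  -1  -1  -3  -1  -3   0   1  -1   1  -3  -3   1  -4  -4  11  -1   0  -3  -2  -4  -2   0  -1
S   1  -1   0   0  -2  -1   0   0  -1  -1  -2   0  -2  -1  -1   4   2  -3  -2  -1   0  -1   0
T   1  -3   1  -1  -2   0  -2  -2  -2   0   0  -1   0  -2   0   2   5  -5  -1   1   0  -1   0
W  -5   0  -7  -4  -2  -1  -1   1  -5  -3  -2  -2  -3   1  -3  -3  -5  20   5  -3  -5  -1  -2
Y  -4   0  -4  -1  -6  -1  -2  -3   0  -1   3  -1  -1   3  -2  -2  -1   5   9   1  -3  -2  -1
V   1  -1  -2  -2  -2  -3  -3  -3  -3   4   1  -2   0   1  -4  -1   1  -3   1   5  -2  -3   0
B   0  -2   4   5  -2  -1   0   0  -2  -2  -1   0  -2  -3  -2   0   0  -5  -3  -2   5   0  -1
Z   0   0  -1   0   0   4   5  -2   0  -3  -1   1  -1  -4   0  -1  -1  -1  -2  -3   0   4   0
X   0  -1   0  -1  -2   0  -1  -1  -1   0   0   0   0  -1  -1   0   0  -2  -1   0  -1   0  -1
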
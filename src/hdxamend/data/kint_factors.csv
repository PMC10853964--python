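# Side-chain correction factors for backbone amide exchange (log10 scale),
# poly-DL-alanine reference, transcribed from the standard literature tables.
# side: L = factor applied to the residue's own amide NH;
#       R = factor applied to the following residue's amide NH.
# term: acid or base catalysis (the water term uses the base factors).
# direction: HD = protium protein exchanging into D2O; DH = deuterated
#            protein exchanging into H2O. The side-chain factors were
#            measured in D2O and are applied to both directions; medium
#            differences enter through reference rates, ion products and pKa.
# Special residue codes: D0/E0 = protonated Asp/Glu (COOH); H+ = charged His;
# H0 = neutral His; C2 = cystine; Pc = cis-proline; NT = N-terminal ammonium
# (R side only); CT = C-terminal COO- and CT0 = C-terminal COOH (L side only).
residue,side,term,value,direction
A,L,acid,0.00,both
A,R,acid,0.00,both
A,L,base,0.00,both
A,R,base,0.00,both
R,L,acid,-0.59,both
R,R,acid,-0.32,both
R,L,base,0.08,both
R,R,base,0.22,both
N,L,acid,-0.58,both
N,R,acid,-0.13,both
N,L,base,0.49,both
N,R,base,0.32,both
D,L,acid,0.90,both
D,R,acid,0.58,both
D,L,base,-0.30,both
D,R,base,-0.18,both
D0,L,acid,-0.90,both
D0,R,acid,-0.12,both
D0,L,base,0.69,both
D0,R,base,0.60,both
C,L,acid,-0.54,both
C,R,acid,-0.46,both
C,L,base,0.62,both
C,R,base,0.55,both
C2,L,acid,-0.74,both
C2,R,acid,-0.58,both
C2,L,base,0.55,both
C2,R,base,0.46,both
G,L,acid,-0.22,both
G,R,acid,0.22,both
G,L,base,0.27,both
G,R,base,0.17,both
Q,L,acid,-0.47,both
Q,R,acid,-0.27,both
Q,L,base,0.06,both
Q,R,base,0.20,both
E,L,acid,-0.90,both
E,R,acid,0.31,both
E,L,base,-0.51,both
E,R,base,-0.15,both
E0,L,acid,-0.60,both
E0,R,acid,-0.27,both
E0,L,base,0.24,both
E0,R,base,0.39,both
H+,L,acid,-0.80,both
H+,R,acid,-0.51,both
H+,L,base,0.80,both
H+,R,base,0.83,both
H0,L,acid,0.00,both
H0,R,acid,0.00,both
H0,L,base,-0.10,both
H0,R,base,0.14,both
I,L,acid,-0.91,both
I,R,acid,-0.59,both
I,L,base,-0.73,both
I,R,base,-0.23,both
L,L,acid,-0.57,both
L,R,acid,-0.13,both
L,L,base,-0.58,both
L,R,base,-0.21,both
K,L,acid,-0.56,both
K,R,acid,-0.29,both
K,L,base,-0.04,both
K,R,base,0.12,both
M,L,acid,-0.64,both
M,R,acid,-0.28,both
M,L,base,-0.01,both
M,R,base,0.11,both
F,L,acid,-0.52,both
F,R,acid,-0.43,both
F,L,base,-0.24,both
F,R,base,0.06,both
P,L,acid,0.00,both
P,R,acid,-0.19,both
P,L,base,0.00,both
P,R,base,-0.24,both
Pc,L,acid,0.00,both
Pc,R,acid,-0.85,both
Pc,L,base,0.00,both
Pc,R,base,0.60,both
S,L,acid,-0.44,both
S,R,acid,-0.39,both
S,L,base,0.37,both
S,R,base,0.30,both
T,L,acid,-0.79,both
T,R,acid,-0.47,both
T,L,base,-0.07,both
T,R,base,0.20,both
W,L,acid,-0.40,both
W,R,acid,-0.44,both
W,L,base,-0.41,both
W,R,base,-0.11,both
Y,L,acid,-0.41,both
Y,R,acid,-0.37,both
Y,L,base,-0.27,both
Y,R,base,0.05,both
V,L,acid,-0.74,both
V,R,acid,-0.30,both
V,L,base,-0.70,both
V,R,base,-0.14,both
NT,R,acid,-1.32,both
NT,R,base,1.62,both
CT,L,acid,0.05,both
CT,L,base,0.00,both
CT0,L,acid,0.96,both
CT0,L,base,-1.80,both
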
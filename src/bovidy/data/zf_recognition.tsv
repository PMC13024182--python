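# Synthetic per-residue base-affinity table for C2H2 zinc-finger contact
# positions (-1, 2, 3, 6 of the recognition helix). Values in [0, 1] are a
# coarse, literature-informed approximation of canonical residue-base
# preferences (Arg->G, Asn/Gln->A, Asp/Glu->C, His->G, aliphatics->T);
# it is a user-replaceable stand-in, not an experimentally fitted model.
# aa	A	C	G	T
A	0.00	0.00	0.00	0.00
C	0.05	0.05	0.05	0.05
D	0.05	0.85	0.05	0.05
E	0.05	0.75	0.15	0.05
F	0.05	0.05	0.05	0.30
G	0.05	0.05	0.05	0.05
H	0.10	0.10	0.75	0.05
I	0.05	0.05	0.05	0.40
K	0.05	0.05	0.70	0.20
L	0.05	0.05	0.05	0.30
M	0.05	0.05	0.05	0.35
N	0.85	0.05	0.05	0.05
P	0.02	0.02	0.02	0.02
Q	0.80	0.05	0.05	0.10
R	0.02	0.02	0.92	0.04
S	0.15	0.15	0.15	0.30
T	0.10	0.10	0.10	0.45
V	0.05	0.05	0.05	0.40
W	0.05	0.05	0.05	0.30
Y	0.05	0.05	0.05	0.35
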
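# Atom counts of the free amino acids, from their molecular formulas
# (e.g. glycine C2H5NO2 = 10 atoms). In-chain residue = free minus 3 (one water).
# columns: residue, formula, total atoms
A	C3H7NO2	13
C	C3H7NO2S	14
D	C4H7NO4	16
E	C5H9NO4	19
F	C9H11NO2	23
G	C2H5NO2	10
H	C6H9N3O2	20
I	C6H13NO2	22
K	C6H14N2O2	24
L	C6H13NO2	22
M	C5H11NO2S	20
N	C4H8N2O3	17
P	C5H9NO2	17
Q	C5H10N2O3	20
R	C6H14N4O2	26
S	C3H7NO3	14
T	C4H9NO3	17
V	C5H11NO2	19
W	C11H12N2O2	27
Y	C9H11NO3	24
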
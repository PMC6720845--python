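# Dipeptide instability weight values (DIWV), Guruprasad K., Reddy B.V.B., Pandit M.W. (1990) Protein Eng. 4(2):155-161.
# Row = first residue of the dipeptide, column = second residue.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	1.0	44.94	-7.49	1.0	1.0	1.0	-7.49	1.0	1.0	1.0	1.0	1.0	20.26	1.0	1.0	1.0	1.0	1.0	1.0	1.0
C	1.0	1.0	20.26	1.0	1.0	1.0	33.6	1.0	1.0	20.26	33.6	1.0	20.26	-6.54	1.0	1.0	33.6	-6.54	24.68	1.0
D	1.0	1.0	1.0	1.0	-6.54	1.0	1.0	1.0	-7.49	1.0	1.0	1.0	1.0	1.0	-6.54	20.26	-14.03	1.0	1.0	1.0
E	1.0	44.94	20.26	33.6	1.0	1.0	-6.54	20.26	1.0	1.0	1.0	1.0	20.26	20.26	1.0	20.26	1.0	1.0	-14.03	1.0
F	1.0	1.0	13.34	1.0	1.0	1.0	1.0	1.0	-14.03	1.0	1.0	1.0	20.26	1.0	1.0	1.0	1.0	1.0	1.0	33.601
G	-7.49	1.0	1.0	-6.54	1.0	13.34	1.0	-7.49	-7.49	1.0	1.0	-7.49	1.0	1.0	1.0	1.0	-7.49	1.0	13.34	-7.49
H	1.0	1.0	1.0	1.0	-9.37	-9.37	1.0	44.94	24.68	1.0	1.0	24.68	-1.88	1.0	1.0	1.0	-6.54	1.0	-1.88	44.94
I	1.0	1.0	1.0	44.94	1.0	1.0	13.34	1.0	-7.49	20.26	1.0	1.0	-1.88	1.0	1.0	1.0	1.0	-7.49	1.0	1.0
K	1.0	1.0	1.0	1.0	1.0	-7.49	1.0	-7.49	1.0	-7.49	33.6	1.0	-6.54	24.64	33.6	1.0	1.0	-7.49	1.0	1.0
L	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	-7.49	1.0	1.0	1.0	20.26	33.6	20.26	1.0	1.0	1.0	24.68	1.0
M	13.34	1.0	1.0	1.0	1.0	1.0	58.28	1.0	1.0	1.0	-1.88	1.0	44.94	-6.54	-6.54	44.94	-1.88	1.0	1.0	24.68
N	1.0	-1.88	1.0	1.0	-14.03	-14.03	1.0	44.94	24.68	1.0	1.0	1.0	-1.88	-6.54	1.0	1.0	-7.49	1.0	-9.37	1.0
P	20.26	-6.54	-6.54	18.38	20.26	1.0	1.0	1.0	1.0	1.0	-6.54	1.0	20.26	20.26	-6.54	20.26	1.0	20.26	-1.88	1.0
Q	1.0	-6.54	20.26	20.26	-6.54	1.0	1.0	1.0	1.0	1.0	1.0	1.0	20.26	20.26	1.0	44.94	1.0	-6.54	1.0	-6.54
R	1.0	1.0	1.0	1.0	1.0	-7.49	20.26	1.0	1.0	1.0	1.0	13.34	20.26	20.26	58.28	44.94	1.0	1.0	58.28	-6.54
S	1.0	33.6	1.0	20.26	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	44.94	20.26	20.26	20.26	1.0	1.0	1.0	1.0
T	1.0	1.0	1.0	20.26	13.34	-7.49	1.0	1.0	1.0	1.0	1.0	-14.03	1.0	-6.54	1.0	1.0	1.0	1.0	-14.03	1.0
V	1.0	1.0	-14.03	1.0	1.0	-7.49	1.0	1.0	-1.88	1.0	1.0	1.0	20.26	1.0	1.0	1.0	-7.49	1.0	1.0	-6.54
W	-14.03	1.0	1.0	1.0	1.0	-9.37	24.68	1.0	1.0	13.34	24.68	13.34	1.0	1.0	1.0	1.0	-14.03	-7.49	1.0	1.0
Y	24.68	1.0	24.68	-6.54	1.0	-7.49	13.34	1.0	1.0	1.0	44.94	1.0	13.34	1.0	-15.91	1.0	-7.49	1.0	-9.37	13.34
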
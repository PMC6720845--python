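# Ionizable-group pKa values, Bjellqvist B. et al. (1993) Electrophoresis 14:1023-1031,
# as used by the Expasy protein-parameter tool.
# columns: group, pKa, charge sign when protonated side (basic) or deprotonated (acidic)
# Nterm:X / Cterm:X rows override the terminal pKa when residue X is terminal.
Nterm	7.5	basic
Cterm	3.55	acidic
Nterm:A	7.59	basic
Nterm:M	7.0	basic
Nterm:S	6.93	basic
Nterm:P	8.36	basic
Nterm:T	6.82	basic
Nterm:V	7.44	basic
Nterm:E	7.7	basic
Cterm:D	4.55	acidic
Cterm:E	4.75	acidic
D	4.05	acidic
E	4.45	acidic
C	9.0	acidic
Y	10.0	acidic
H	5.98	basic
K	10.0	basic
R	12.0	basic
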
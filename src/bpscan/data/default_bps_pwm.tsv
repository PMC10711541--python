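# bpscan default branch point PWM (package-authored; consensus 'nnyTrAy').
# A degenerate heptamer model with conserved T at position 4 and the branch
# point adenine at position 6. Columns are base probabilities per position.
pos	A	C	G	T
1	0.35	0.28	0.15	0.22
2	0.22	0.28	0.15	0.35
3	0.06	0.38	0.04	0.52
4	0.02	0.02	0.02	0.94
5	0.55	0.05	0.35	0.05
6	0.94	0.02	0.02	0.02
7	0.06	0.52	0.04	0.38
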
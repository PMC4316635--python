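five_prime	A	C	G	T	three_prime
A	1.45	8.96	3.65	7.80	A
A	20.02	8.67	14.44	12.95	C
A	5.80	9.94	10.98	45.96	G
A	3.77	4.87	9.75	10.01	T
C	23.71	10.19	15.04	12.94	A
C	50.77	19.58	39.09	28.88	C
C	19.76	18.91	49.82	42.98	G
C	21.38	4.89	27.02	18.49	T
G	8.80	11.28	9.45	42.20	A
G	18.25	19.31	49.97	41.61	C
G	10.98	13.30	45.92	97.73	G
G	5.59	6.67	21.05	49.81	T
T	4.60	4.14	10.26	8.10	A
T	16.36	4.98	29.40	17.30	C
T	5.42	5.80	22.22	59.07	G
T	2.28	1.79	20.84	5.29	T
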
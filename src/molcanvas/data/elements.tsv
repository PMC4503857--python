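symbol	atomic_number	atomic_mass	covalent_radius	default_valences	cpk_color	jmol_color
H	1	1.0080	0.31	1	FFFFFF	FFFFFF
He	2	4.0030	0.28	0	FFC0CB	D9FFFF
Li	3	6.9410	1.28	1	B22222	CC80FF
Be	4	9.0120	0.96	2	FF1493	C2FF00
B	5	10.8120	0.84	3	FF1493	FFB5B5
C	6	12.0110	0.76	4	C8C8C8	909090
N	7	14.0070	0.71	3,5	8F8FFF	3050F8
O	8	15.9990	0.66	2	F00000	FF0D0D
F	9	18.9980	0.57	1	DAA520	90E050
Ne	10	20.1800	0.58	0	FF1493	B3E3F5
Na	11	22.9900	1.66	1	0000FF	AB5CF2
Mg	12	24.3050	1.41	2	228B22	8AFF00
Al	13	26.9820	1.21	3	808090	BFA6A6
Si	14	28.0860	1.11	4	DAA520	F0C8A0
P	15	30.9740	1.07	3,5	FFA500	FF8000
S	16	32.0670	1.05	2,4,6	FFC832	FFFF30
Cl	17	35.4530	1.02	1	00FF00	1FF01F
Ar	18	39.9480	1.06	0	FF1493	80D1E3
K	19	39.0980	2.03	1	FF1493	8F40D4
Ca	20	40.0780	1.76	2	808090	3DFF00
Sc	21	44.9560	1.70		FF1493	E6E6E6
Ti	22	47.8670	1.60		FF1493	BFC2C7
V	23	50.9440	1.53		FF1493	A6A6AB
Cr	24	51.9960	1.39		FF1493	8A99C7
Mn	25	54.9380	1.39		808090	9C7AC7
Fe	26	55.8450	1.32		FFA500	E06633
Co	27	58.9330	1.26		FF1493	F090A0
Ni	28	58.6930	1.24		FF1493	50D050
Cu	29	63.5460	1.32		A52A2A	C88033
Zn	30	65.3900	1.22		A52A2A	7D80B0
Ga	31	69.7230	1.22	3	FF1493	C28F8F
Ge	32	72.6100	1.20	4	FF1493	668F8F
As	33	74.9220	1.19	3,5	FF1493	BD80E3
Se	34	78.9600	1.20	2,4,6	FF1493	FFA100
Br	35	79.9040	1.20	1	A52A2A	A62929
Kr	36	83.8000	1.16	0	FF1493	5CB8D1
Rb	37	85.4680	2.20	1	FF1493	702EB0
Sr	38	87.6200	1.95	2	FF1493	00FF00
Y	39	88.9060	1.90		FF1493	94FFFF
Zr	40	91.2240	1.75		FF1493	94E0E0
Nb	41	92.9060	1.64		FF1493	73C2C9
Mo	42	95.9400	1.54		FF1493	54B5B5
Tc	43	98.0000	1.47		FF1493	3B9E9E
Ru	44	101.0700	1.46		FF1493	248F8F
Rh	45	102.9060	1.42		FF1493	0A7D8C
Pd	46	106.4200	1.39		FF1493	006985
Ag	47	107.8680	1.45		FF1493	C0C0C0
Cd	48	112.4120	1.44		FF1493	FFD98F
In	49	114.8180	1.42	3	FF1493	A67573
Sn	50	118.7110	1.39	4,2	FF1493	668080
Sb	51	121.7600	1.39	3,5	FF1493	9E63B5
Te	52	127.6000	1.38	2,4,6	FF1493	D47A00
I	53	126.9040	1.39	1	A020F0	940094
Xe	54	131.2900	1.40	0	FF1493	429EB0
Cs	55	132.9050	2.44	1	FF1493	57178F
Ba	56	137.3280	2.15	2	FFA500	00C900
La	57	138.9060	2.07		FF1493	70D4FF
Ce	58	140.1160	2.04		FF1493	FFFFC7
Pr	59	140.9080	2.03		FF1493	D9FFC7
Nd	60	144.2400	2.01		FF1493	C7FFC7
Pm	61	145.0000	1.99		FF1493	A3FFC7
Sm	62	150.3600	1.98		FF1493	8FFFC7
Eu	63	151.9640	1.98		FF1493	61FFC7
Gd	64	157.2500	1.96		FF1493	45FFC7
Tb	65	158.9250	1.94		FF1493	30FFC7
Dy	66	162.5000	1.92		FF1493	1FFFC7
Ho	67	164.9300	1.92		FF1493	00FF9C
Er	68	167.2600	1.89		FF1493	00E675
Tm	69	168.9340	1.90		FF1493	00D452
Yb	70	173.0400	1.87		FF1493	00BF38
Lu	71	174.9670	1.87		FF1493	00AB24
Hf	72	178.4900	1.75		FF1493	4DC2FF
Ta	73	180.9480	1.70		FF1493	4DA6FF
W	74	183.8400	1.62		FF1493	2194D6
Re	75	186.2070	1.51		FF1493	267DAB
Os	76	190.2300	1.44		FF1493	266696
Ir	77	192.2170	1.41		FF1493	175487
Pt	78	195.0780	1.36		FF1493	D0D0E0
Au	79	196.9670	1.36		DAA520	FFD123
Hg	80	200.5900	1.32		FF1493	B8B8D0
Tl	81	204.3830	1.45	3,1	FF1493	A6544D
Pb	82	207.2000	1.46	4,2	FF1493	575961
Bi	83	208.9800	1.48	3,5	FF1493	9E4FB5
Po	84	209.0000	1.40	2	FF1493	AB5C00
At	85	210.0000	1.50	1	FF1493	754F45
Rn	86	222.0000	1.50	0	FF1493	428296
Fr	87	223.0000	2.60	1	FF1493	420066
Ra	88	226.0000	2.21	2	FF1493	007D00
Ac	89	227.0000	2.15		FF1493	70ABFA
Th	90	232.0380	2.06		FF1493	00BAFF
Pa	91	231.0360	2.00		FF1493	00A1FF
U	92	238.0290	1.96		FF1493	008FFF
Np	93	237.0000	1.90		FF1493	0080FF
Pu	94	244.0000	1.87		FF1493	006BFF
Am	95	243.0000	1.80		FF1493	545CF2
Cm	96	247.0000	1.69		FF1493	785CE3
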
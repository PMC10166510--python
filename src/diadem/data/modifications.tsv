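id	name	delta_mass	sites
1	Acetyl	42.010565	K,S,T,nterm
2	Amidated	-0.984016	cterm
4	Carbamidomethyl	57.021464	C
5	Carbamyl	43.005814	K,R,C,nterm
7	Deamidated	0.984016	N,Q
21	Phospho	79.966331	S,T,Y
28	Gln->pyro-Glu	-17.026549	Q
34	Methyl	14.015650	K,R,nterm
35	Oxidation	15.994915	M,W,H,P
36	Dimethyl	28.031300	K,R,nterm
37	Trimethyl	42.046950	K,R
58	Propionyl	56.026215	K,nterm
64	Succinyl	100.016044	K
121	GG	114.042927	K
122	Formyl	27.994915	K,S,T,nterm
345	Trioxidation	47.984744	C
354	Nitro	44.985078	W,Y
425	Dioxidation	31.989829	M,W
1289	Butyryl	70.041865	K
1363	Crotonyl	68.026215	K
1848	Glutaryl	114.031694	K
746	Hex	162.052824	K,R,nterm
43	HexNAc	203.079373	N,S,T
45	Myristoyl	210.198366	K,C,G,nterm
47	Palmitoyl	238.229666	K,C,S,T
3	Biotin	226.077598	K,nterm
6	Malonyl	86.000394	K
253	Cation:Na	21.981943	D,E,cterm
530	Cation:K	37.955882	D,E,cterm
23	Dehydrated	-18.010565	S,T,D,Y
385	Ammonia-loss	-17.026549	N,nterm
737	TMT6plex	229.162932	K,nterm
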
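gene	species	paml_omega0	paml_omega1	paml_p	paml_q	busted_p	busted_q	relax_k	relax_p	relax_q
ADAMTS18	C. cochlearius	0.2385	0.2385	4.639E-03	8.160E-02	0.5	5.21E-01	1.16	0.002	0.0184
ALDH1A3	C. cochlearius	0.0315	0.0315	8.359E-02	4.524E-01	0.002	8.39E-02	0.32	0.006	0.0378
CACNB2	C. cochlearius	0.1851	0.1851	1.489E-01	5.051E-01	0.5	5.21E-01	0	0.001	0.0108
CCDC66	C. cochlearius	0.5134	0.0175	2.815E-06	9.902E-05	0.5	5.21E-01	1	1	0.8932
CRB1	C. cochlearius	0.1249	0.0212	3.556E-07	1.668E-05	0.0035	8.39E-02	2.51	5.349E-05	0.0011
EPAS1	C. cochlearius	0.2276	0.2276	1.937E-01	6.102E-01	0.5	5.00E-01	0	0.001	0.0073
EPHB1	C. cochlearius	0.0485	0.0485	2.102E-02	2.201E-01	0.5	5.21E-01	15.9	1.384E-05	0.0003
FOXP2	C. cochlearius	0.1829	0.1829	9.362E-02	4.841E-01	0.5	5.21E-01	0	0.005	0.0374
JAG1	C. cochlearius	0.0328	0.0328	1.439E-01	5.051E-01	0.5	5.21E-01	0	0.007	0.0418
MAP3K1	C. cochlearius	0.2610	0.2610	5.521E-02	3.237E-01	0.5	5.21E-01	0	0.001	0.0108
MED1	C. cochlearius	0.0319	0.1132	1.036E-03	2.429E-02	6.801E-05	9.64E-03	0.64	0.0004	0.0062
MEGF11	C. cochlearius	0.1747	0.1747	2.070E-02	2.201E-01	0.5	5.21E-01	46.41	0.002	0.0184
MYO7A	C. cochlearius	0.0001	0.0001	1	1	0.5	5.00E-01	15.7	0.006	0.0176
OPA1	C. cochlearius	0.1855	0.1855	3.263E-02	3.061E-01	0.5	5.21E-01	0	7.505E-06	0.0002
OPN4	C. cochlearius	0.0361	0.0361	1.507E-01	5.051E-01	0.5	5.21E-01	0	5.853E-07	3.503E-05
PDGFRB	C. cochlearius	0.0754	0.0077	4.477E-04	1.260E-02	0.5	5.21E-01	1.12	0.594	0.7279
RNF2	C. cochlearius	0.0442	0.0203	0	0	0.5	5.21E-01	1.21	0.88	0.8917
SLC25A25	C. cochlearius	0.0099	0.0099	4.839E-01	7.612E-01	0.003	8.39E-02	18.88	7.371E-10	8.822E-08
SLC4A10	C. cochlearius	0.1424	0.1424	3.054E-01	6.319E-01	0.5	5.21E-01	0	8.979E-05	0.0015
SLC7A11	C. cochlearius	0.2571	0.2571	4.125E-03	9.096E-02	0.5	5.00E-01	0	0.002	0.0098
SMAD3	C. cochlearius	0.0281	0.0281	5.467E-01	8.013E-01	0.5	5.21E-01	0	0.0003	0.0054
SOX14	C. cochlearius	0.0151	0.0151	9.751E-01	1	0.5	5.21E-01	0	7.505E-06	0.0002
TULP3	C. cochlearius	0.2277	0.1016	7.272E-230	5.116E-228	0.02	4.05E-01	1.58	0.131	0.3038
WDR19	C. cochlearius	0.1118	0.1118	4.995E-02	3.671E-01	0.5	5.00E-01	2.3	0.003	0.0110
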
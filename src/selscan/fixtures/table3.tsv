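gene	species	paml_omega0	paml_omega1	paml_p	paml_q	busted_p	busted_q	relax_k	relax_p	relax_q
ADAMTS18	N. nycticorax	0.2385	0.2385	5.158E-01	8.936E-01	0.5	0.46323	0	0.005	0.0231
ATP8A2	N. nycticorax	0.2646	0.0001	9.826E-05	3.301E-03	0.5	0.50859	1.17	0.002	0.0136
CCDC66	N. nycticorax	0.3254	2.5296	1.639E-06	5.679E-05	1.054E-18	6.646E-17	3.86	6.22154E-14	1.730E-12
CDON	N. nycticorax	0.2713	1.0674	0	0	4.277E-18	1.796E-16	10.54	2.398E-26	1.335E-24
CHD7	N. nycticorax	0.0817	0.0817	9.238E-01	9.900E-01	1.837E-20	2.315E-18	35.59	0.0001	0.0015
CRYBA1	N. nycticorax	0.0477	0.2343	2.176E-04	4.310E-03	0.0001	0.0013	0.32	3.122E-06	3E-05
CTNS	N. nycticorax	0.4024	0.4024	6.838E-02	3.833E-01	0.0011	0.0108	10.39	0	0
EPAS1	N. nycticorax	0.2276	0.2276	8.291E-01	1	0.5	0.4295	0.11	0.002	0.008
FAT3	N. nycticorax	0.0913	0.0913	8.275E-02	3.955E-01	1.030E-09	2.165E-08	50	1.99E-11	2.768E-10
FGFR2	N. nycticorax	0.0738	0.0738	3.157E-01	6.267E-01	0.5	0.4632	0.44	0.003	0.0151
FOXP2	N. nycticorax	0.1829	0.1829	1.735E-01	4.966E-01	0.5	0.4632	0	0.011	0.0394
GNA11	N. nycticorax	0.0001	0.3321	6.565E-04	1.137E-02	0.5	0.4632	0.15	0.008	0.0318
GNAQ	N. nycticorax	0.1753	0.1753	4.591E-02	2.204E-01	0.5	0.5085	0	0.004	0.0218
GNAT1	N. nycticorax	0.0217	0.1128	5.745E-04	1.025E-02	0.5	0.525	0.89	0.648	1
HDAC1	N. nycticorax	0.0411	0.0411	1.530E-01	4.903E-01	0.5	0.4632	0	0.017	0.05
HPS1	N. nycticorax	0.1729	0.1729	9.458E-01	9.900E-01	0.019	0.1408	0.61	0.01	0.0371
IMPG1	N. nycticorax	0.2561	0.6748	2.942E-04	4.943E-03	8.481E-12	2.760E-10	0.5	8.008E-13	2.186E-11
IMPG2	N. nycticorax	0.3791	0.3791	7.494E-01	1	2.423E-11	2.290E-10	39.63	0.013	0.0464
MDM1	N. nycticorax	0.3542	0.3542	9.218E-01	9.900E-01	0.002	0.018	1.18	0.476	0.6307
MFN2	N. nycticorax	0.0505	0.0505	2.719E-01	5.703E-01	8.329E-05	0.0011	5.49	6.713E-05	0.0006
MITF	N. nycticorax	0.0183	0.0183	7.086E-01	9.484E-01	4.630E-10	1.167E-08	7.68	0.761	0.8066
NHS	N. nycticorax	0.1380	0.1380	1.199E-01	4.903E-01	0.5	0.4632	0.09	0.001	0.0055
OLFM3	N. nycticorax	0.1720	0.9096	4.110E-07	9E-06	3.985E-10	2.510E-09	0	1.894E-12	3.373E-11
OPA1	N. nycticorax	0.1855	0.1855	6.913E-02	3.833E-01	0.031	0.2055	0	0.001	0.0055
OPN4	N. nycticorax	0.0361	0.0361	5.956E-02	3.589E-01	0.0001	0.0014	13.37	9.919E-13	2.208E-11
PAX6	N. nycticorax	0.1595	0.1595	9.914E-01	9.900E-01	0.5	0.4632	0.15	0.007	0.0288
PDGFRB	N. nycticorax	0.0564	0.4014	1.792E-04	4.139E-03	0.5	0.4632	5.54	0.853	0.8183
RPE65	N. nycticorax	0.1523	0.1523	1.923E-01	5.030E-01	0.5	0.4632	0.09	0.001	0.0055
RPL24	N. nycticorax	0.0089	1.4164	0	0	1.963E-07	3E-06	29.42	6.06E-12	9.635E-11
RRM1	N. nycticorax	0.0198	0.6076	8.728E-06	2.419E-04	0.0024	0.0209	0.07	0.002	0.0106
SH3PXD2B	N. nycticorax	0.1368	0.1368	5.E-02	3.300E-01	1.790E-10	5.641E-09	17.08	1.529E-12	2.838E-11
SKI	N. nycticorax	0.0631	0.6871	0	0	8.824E-08	1.5E-06	0.2	3.898E-23	1.446E-21
SLC4A10	N. nycticorax	0.1424	0.1424	3.260E-01	6.365E-01	0.417	0.4632	0	9.367E-05	0.0008
SLC7A11	N. nycticorax	0.2571	0.2571	9.602E-01	1	7.536E-05	0.0003	2.37	0.001	0.0059
SMAD3	N. nycticorax	0.0281	0.0281	7.100E-01	9.484E-01	0.5	0.4632	0	0.0002	0.0021
TTC8	N. nycticorax	0.2426	0.2426	2.313E-02	1.554E-01	0.5	0.5085	0	0.001	0.0091
UCHL3	N. nycticorax	0.1590	0.1590	1.460E-01	3.774E-01	0.5	0.5085	0	0.007	0.0318
UNC119	N. nycticorax	0.0264	0.0264	4.437E-03	6.833E-02	0.001	0.0105	50	0.006	0.0256
VEGFA	N. nycticorax	0.6017	0.6017	8.976E-01	9.9E-01	0.003	0.0236	46.91	3.583E-05	0.0003
WDR19	N. nycticorax	0.1118	0.1118	4.362E-01	1	5.819E-21	1.099E-19	0.97	0.889	0.85
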
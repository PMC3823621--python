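gene_symbol	description	correlation_factor	log2_fold_change	power
Socs1	Suppressor of cytokine signaling 1	0.89	2.744	1.96E-08
Gpr85	G protein-coupled receptor 85	0.92	2.211	1.67E-07
Ell2	Elongation factor RNA polymerase II 2	0.93	2.094	6.35E-10
Fam102b	Family with sequence similarity 102, member B	0.93	1.843	2.05E-08
B3gnt5	UDP-GlcNAc:betaGal beta-1,3-N-acetylglucosaminyltransferase 5	0.95	1.721	1.74E-08
Fgl2	Fibrinogen-like protein 2	0.87	1.695	4.13E-07
Ets1	E26 avian leukemia oncogene 1, 5' domain	0.91	1.523	8.64E-08
Hivep2	Human immunodeficiency virus type I enhancer binding protein 2	0.95	1.476	5.03E-08
Mier3	Mesoderm induction early response 1, family member 3	0.95	1.403	4.90E-08
Cebpb	CCAAT/enhancer binding protein (C/EBP), beta	0.86	1.386	5.30E-07
Il13ra1	Interleukin 13 receptor, alpha 1	0.88	1.382	1.24E-07
Rapgef2	Rap guanine nucleotide exchange factor (GEF) 2	0.94	1.310	1.39E-07
Spred1	Sprouty protein with EVH-1 domain 1, related sequence	0.96	1.254	1.59E-07
S1pr1	Sphingosine-1-phosphate receptor 1	0.89	1.249	9.70E-08
Ikbke	Inhibitor of kappaB kinase epsilon	0.94	1.234	4.68E-07
Sgk3	Serum/glucocorticoid regulated kinase 3	0.92	1.035	5.15E-08
Samhd1	SAM domain and HD domain, 1	0.92	1.023	9.24E-08
Gdf6	Growth differentiation factor 6	0.85	0.975	4.59E-05
Morc3	Microrchidia 3	0.87	0.888	1.66E-06
Myo1d	Myosin ID	0.80	0.837	3.79E-06
Rictor	RPTOR independent companion of MTOR, complex 2	0.92	0.837	2.27E-07
Tle4	Transducin-like enhancer of split 4, homolog of Drosophila E(spl)	0.96	0.795	8.86E-07
Satb2	Special AT-rich sequence binding protein 2	0.74	0.790	6.62E-05
Atad2b	ATPase family, AAA domain containing 2B	0.93	0.787	1.19E-06
Hif1a	Hypoxia inducible factor 1, alpha subunit	0.96	0.760	1.10E-06
Cd47	CD47 antigen (Rh-related antigen, integrin-associated signal transducer)	0.93	0.750	7.77E-06
Vcpip1	Valosin containing protein (p97)/p47 complex interacting protein 1	0.92	0.706	1.26E-06
Asf1a	ASF1 anti-silencing function 1 homolog A (S. cerevisiae)	0.91	0.694	1.84E-06
Whsc1l1	Wolf-Hirschhorn syndrome candidate 1-like 1 (human)	0.91	0.663	4.19E-06
Cdk14	Cyclin-dependent kinase 14	0.91	0.660	6.07E-05
Syvn1	Synovial apoptosis inhibitor 1, synoviolin	0.82	0.641	3.91E-05
G3bp2	GTPase activating protein (SH3 domain) binding protein 2	0.91	0.623	4.05E-06
Xiap	X-linked inhibitor of apoptosis	0.96	0.611	5.02E-06
Lrrc59	Leucine rich repeat containing 59	0.85	0.595	1.41E-05
Kalrn	Kalirin, RhoGEF kinase	0.86	0.590	3.97E-06
Rab22a	RAB22A, member RAS oncogene family	0.86	0.578	6.59E-06
Med13l	Mediator complex subunit 13-like	0.73	0.542	6.31E-06
Pkn2	protein kinase N2	0.91	0.528	1.28E-05
Carhsp1	Calcium regulated heat stable protein 1	0.68	0.514	6.13E-05
Dmtf1	Cyclin D binding myb-like transcription factor 1	0.86	0.506	1.36E-05
Arl5b	ADP-ribosylation factor-like 5B	0.96	0.476	3.89E-05
Dennd1b	DENN/MADD domain containing 1B	0.81	0.476	1.57E-05
Kbtbd2	Kelch repeat and BTB (POZ) domain containing 2	0.94	0.451	5.61E-05
Ythdc2	YTH domain containing 2	0.89	0.426	9.64E-05
Fam105a	Family with sequence similarity 105, member A	-0.94	-3.370	7.86E-10
Inpp5d	Inositol polyphosphate-5-phosphatase D	-0.94	-2.482	3.53E-10
Arvcf	Armadillo repeat gene deleted in velo-cardio-facial syndrome	-0.92	-2.036	1.32E-07
Rapgef5	Rap guanine nucleotide exchange factor (GEF) 5	-0.92	-1.741	1.02E-08
Ssh2	Slingshot homolog 2 (Drosophila)	-0.88	-1.661	4.28E-07
Tspan14	Tetraspanin 14	-0.95	-1.537	2.80E-09
Myb	Myeloblastosis oncogene	-0.60	-1.434	2.77E-05
Reck	Reversion-inducing-cysteine-rich protein with kazal motifs	-0.94	-1.369	1.49E-07
Lat2	Linker for activation of T cells family, member 2	-0.91	-1.270	2.69E-07
Arhgap18	Rho GTPase activating protein 18	-0.92	-1.219	5.53E-08
Card11	Caspase recruitment domain family, member 11	-0.56	-1.165	5.49E-05
Mafb	v-maf musculoaponeurotic fibrosarcoma oncogene family, protein B (avian)	-0.78	-1.130	4.54E-08
Socs6	Suppressor of cytokine signaling 6	-0.66	-1.124	2.14E-07
Tmem144	Transmembrane protein 144	-0.83	-1.107	3.68E-06
Ddo	D-aspartate oxidase	-0.76	-1.102	3.64E-07
Entpd1	Ectonucleoside triphosphate diphosphohydrolase 1	-0.68	-1.077	1.05E-07
Rcbtb2	Regulator of chromosome condensation (RCC1) and BTB (POZ) domain containing protein 2	-0.79	-1.067	1.60E-06
Reps2	RALBP1 associated Eps domain containing protein 2	-0.63	-1.053	7.89E-07
Arhgap5	Rho GTPase activating protein 5	-0.77	-1.036	1.08E-06
Tcf7l2	Transcription factor 7-like 2, T-cell specific, HMG-box	-0.98	-0.9855	6.03E-06
Rreb1	Ras responsive element binding protein 1	-0.91	-0.986	1.43E-07
Agl	Amylo-1,6-glucosidase, 4-alpha-glucanotransferase	-0.93	-0.960	2.82E-07
Add3	Adducin 3 (gamma)	-0.80	-0.905	1.83E-07
Antxr2	Anthrax toxin receptor 2	-0.88	-0.903	1.19E-06
Satb1	Special AT-rich sequence binding protein 1	-0.79	-0.873	1.98E-06
Rnf166	Ring finger protein 166	-0.94	-0.866	5.91E-06
Enpp1	Ectonucleotide pyrophosphatase/phosphodiesterase 1	-0.75	-0.849	2.10E-06
Meis1	Meis homeobox 1	-0.88	-0.849	1.52E-05
Mphosph9	M-phase phosphoprotein 9	-0.84	-0.817	3.11E-06
Nfia	Nuclear factor I/A	-0.84	-0.809	2.78E-07
Lcorl	Ligand dependent nuclear receptor corepressor-like	-0.93	-0.791	4.67E-07
Ski	Ski sarcoma viral oncogene homolog (avian)	-0.90	-0.775	2.64E-05
Dcun1d4	DCN1, defective in cullin neddylation 1, domain containing 4 (S. cerevisiae)	-0.86	-0.758	5.91E-06
Syne1	Synaptic nuclear envelope 1	-0.88	-0.727	4.04E-06
Sort1	Sortilin 1	-0.89	-0.722	6.00E-06
Rell1	RELT-like 1	-0.72	-0.711	8.42E-06
Dixdc1	DIX domain containing 1	-0.73	-0.705	1.40E-05
Csf1r	Colony stimulating factor 1 receptor	-0.80	-0.692	8.23E-06
Haus3	HAUS augmin-like complex, subunit 3	-0.82	-0.680	1.44E-05
Gabra4	Gamma-aminobutyric acid (GABA) A receptor, subunit alpha 4	-0.83	-0.665	2.57E-06
Akap10	A kinase (PRKA) anchor protein 10	-0.91	-0.660	1.65E-05
Cep68	Centrosomal protein 68	-0.67	-0.659	8.79E-05
Rufy2	RUN and FYVE domain-containing 2	-0.96	-0.634	3.60E-06
Megf10	Multiple EGF-like-domains 10	-0.90	-0.611	1.75E-05
Tbck	TBC1 domain containing kinase	-0.91	-0.600	9.79E-06
Zc3h12b	Zinc finger CCCH-type containing 12B	-0.79	-0.597	4.85E-05
Fads1	Fatty acid desaturase 1	-0.91	-0.585	4.98E-06
Zmym2	Zinc finger, MYM-type 2	-0.87	-0.581	4.63E-05
Terf1	Telomeric repeat binding factor 1	-0.88	-0.574	2.03E-05
Tnpo1	Transportin 1	-0.86	-0.558	8.55E-05
Igsf11	Immunoglobulin superfamily, member 11	-0.67	-0.540	7.77E-06
Mbtd1	Mbt domain containing 1	-0.83	-0.533	5.42E-05
Trim2	Tripartite motif-containing 2	-0.76	-0.515	2.27E-05
Nudt4	Nudix (nucleoside diphosphate linked moiety X)-type motif 4	-0.78	-0.510	1.59E-05
Ogn	Osteoglycin	-0.72	-0.496	9.79E-05
Ergic1	Endoplasmic reticulum-golgi intermediate compartment (ERGIC) 1	-0.91	-0.480	2.18E-05
Ankrd12	Ankyrin repeat domain 12	-0.63	-0.479	1.91E-05
Csnk1g2	Casein kinase 1, gamma 2	-0.94	-0.479	1.96E-05
Pskh1	Protein serine kinase H1	-0.95	-0.467	2.98E-05
Slc39a10	Solute carrier family 39 (zinc transporter), member 10	-0.86	-0.448	3.47E-05
Clcn3	Chloride channel 3	-0.74	-0.442	7.51E-05
Grsf1	G-rich RNA sequence binding factor 1	-0.81	-0.422	4.48E-05
Rcor1	REST corepressor 1	-0.86	-0.417	3.78E-05
Asph	Aspartate-beta-hydroxylase	-0.85	-0.414	3.94E-05
Ikbip	IKBKB interacting protein	-0.86	-0.411	9.88E-05
Dclre1a	DNA cross-link repair 1A, PSO2 homolog (S. cerevisiae)	-0.90	-0.372	7.23E-05
Tram1	Translocating chain-associating membrane protein 1	-0.86	-0.365	7.87E-05
Fbxo22	F-box protein 22	-0.90	-0.351	7.44E-05
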
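genus	v4_illumina_reads	v4_from_rocits	expected_rocits	initial_clustering	after_full_analysis	n_genera_clusters	largest_cluster
Pseudomonas	81163	1115	1230	1022	618	14	753
Flavobacterium	55508	996	841	944	666	11	806
Microccaceae	42342	321	642	277	195	4	235
Bacillus	32414	656	491	585	425	8	472
Duganella	12681	166	192	140	92	2	134
Mucilaginibacter	9373	180	142	159	107	5	107
Bradyrhizobium	4135	86	63	63	41	3	50
Pedobacter	1723	108	26	84	66	1	84
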
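cluster_id	member_index	mirna_id	annotation_family	phylo_family	origin_lineage
c01	0	dme-mir-999	mir-999	mir-999	Insects
c01	1	dme-mir-4969	mir-4969	mir-4969	Melanogaster
c02	0	dme-mir-982	mir-982	mir-982	Drosophila
c02	1	dme-mir-303	mir-303	mir-303	Melanogaster
c02	2	dme-mir-983-1	mir-983	mir-983	Melanogaster
c02	3	dme-mir-983-2	mir-983	mir-983	Melanogaster
c02	4	dme-mir-984	mir-984	mir-984	Melanogaster
c03	0	dme-mir-969	mir-969	mir-969	Drosophila
c03	1	dme-mir-210	mir-210	mir-210	Metazoans
c04	0	dme-mir-124	mir-124	mir-124	Metazoans
c04	1	dme-mir-287	mir-287	mir-287	Drosophila
c05	0	dme-mir-972	mir-972	mir-972	Insects
c05	1	dme-mir-973	mir-973	mir-973	Drosophila
c05	2	dme-mir-974	mir-974	mir-974	Drosophila
c05	3	dme-mir-2499	mir-2499	mir-2499	Melanogaster
c05	4	dme-mir-4966	mir-4966	mir-4966	Melanogaster
c05	5	dme-mir-975	mir-975	mir-975	Drosophila
c05	6	dme-mir-976	mir-976	mir-976	Drosophila
c05	7	dme-mir-977	mir-977	mir-977	Drosophila
c05	8	dme-mir-978	mir-978	mir-978	Drosophila
c05	9	dme-mir-979	mir-979	mir-979	Drosophila
c06	0	dme-mir-959	mir-959	mir-959	Insects
c06	1	dme-mir-960	mir-960	mir-960	Drosophila
c06	2	dme-mir-961	mir-961	mir-961	Drosophila
c06	3	dme-mir-962	mir-962	mir-962	Drosophila
c06	4	dme-mir-963	mir-963	mir-963	Drosophila
c06	5	dme-mir-964	mir-964	mir-964	Drosophila
c07	0	dme-mir-1002	mir-1002	mir-1002	Drosophila
c07	1	dme-mir-968	mir-968	mir-968	Insects
c08	0	dme-mir-281-2	mir-281	mir-281	Drosophila
c08	1	dme-mir-281-1	mir-281	mir-281	Drosophila
c09	0	dme-mir-310	mir-310	mir-310	Drosophila
c09	1	dme-mir-311	mir-310	mir-310	Drosophila
c09	2	dme-mir-312	mir-310	mir-310	Drosophila
c09	3	dme-mir-313	mir-310	mir-310	Drosophila
c09	4	dme-mir-2498	mir-2498	mir-2498	Melanogaster
c09	5	dme-mir-991	mir-991	mir-991	Melanogaster
c09	6	dme-mir-992	mir-992	mir-992	Melanogaster
c10	0	dme-mir-6-3	mir-6	mir-6	Insects
c10	1	dme-mir-6-2	mir-6	mir-6	Insects
c10	2	dme-mir-6-1	mir-6	mir-6	Insects
c10	3	dme-mir-5	mir-5	mir-5	Insects
c10	4	dme-mir-4	mir-4	mir-4	Insects
c10	5	dme-mir-286	mir-286	mir-286	Protostomes
c10	6	dme-mir-3	mir-3	mir-3	Insects
c10	7	dme-mir-309	mir-309	mir-309	Insects
c11	0	dme-mir-998	mir-998	mir-998	Insects
c11	1	dme-mir-11	mir-11	mir-11	Protostomes
c12	0	dme-mir-994	mir-994	mir-994	Insects
c12	1	dme-mir-318	mir-318	mir-318	Protostomes
c13	0	dme-mir-279	mir-279	mir-279	Insects
c13	1	dme-mir-996	mir-996	mir-279	Insects
c14	0	dme-mir-9c	mir-9	mir-9c	Insects
c14	1	dme-mir-306	mir-306	mir-306	Insects
c14	2	dme-mir-79	mir-79	mir-79	Insects
c14	3	dme-mir-9b	mir-9	mir-9b	Insects
c15	0	dme-mir-283	mir-283	mir-283	Metazoans
c15	1	dme-mir-304	mir-304	mir-304	Protostomes
c15	2	dme-mir-12	mir-12	mir-12	Protostomes
c16	0	dme-mir-275	mir-275	mir-275	Metazoans
c16	1	dme-mir-305	mir-305	mir-305	Protostomes
c17	0	dme-mir-317	mir-317	mir-317	Protostomes
c17	1	dme-mir-277	mir-277	mir-277	Protostomes
c17	2	dme-mir-34	mir-34	mir-34	Metazoans
c18	0	dme-mir-13b-1	mir-2	mir-2	Protostomes
c18	1	dme-mir-13a	mir-2	mir-2	Protostomes
c18	2	dme-mir-2c	mir-2	mir-2	Protostomes
c19	0	dme-mir-2a-2	mir-2	mir-2	Protostomes
c19	1	dme-mir-2a-1	mir-2	mir-2	Protostomes
c19	2	dme-mir-2b-2	mir-2	mir-2	Protostomes
c20	0	dme-mir-92a	mir-92	mir-92	Metazoans
c20	1	dme-mir-92b	mir-92	mir-92	Metazoans
c21	0	dme-mir-100	mir-100	mir-100	Metazoans
c21	1	dme-let-7	let-7	let-7	Metazoans
c21	2	dme-mir-125	mir-125	mir-125	Metazoans
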
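cluster_id	name	source	lineage	original_mirna	notes
c01	999/4969	NewHairpin	Melanogaster	dme-mir-999	Original miRNA: mir-999
c02	982/303/983-1/983-2/984	NewHairpin	Melanogaster		Multiple emergence within a conserved gene
c03	969/210	NewHairpin	Drosophila	dme-mir-210	Original microRNA: mir-210
c04	124/287	NewHairpin	Drosophila	dme-mir-124	Original microRNA: mir-124
c05	972/973/974/2499/4966/975/976/977/978/979	NewHairpin	Drosophila
c06	959/960/961/962/963/964	NewHairpin	Drosophila
c07	1002/968	NewHairpin	Drosophila
c08	281-2/281-1	Duplication	Drosophila
c09	310/311/312/313/2498/991/992	Duplication	Drosophila		Probably two clusters: 310/311/312/313 and 2498/991/992
c10	6-3/6-2/6-1/5/4/286/3/309	NewHairpin	Insects		Cluster may be older
c11	998/11	NewHairpin	Insects
c12	994/318	NewHairpin	Insects
c13	279/996	Duplication	Insects
c14	9c/306/79/9b	Unknown	Insects
c15	283/304/12	NewHairpin	Protostomes
c16	275/305	NewHairpin	Protostomes
c17	317/277/34	NewHairpin	Protostomes	dme-mir-34	Original microRNA: mir-34
c18	13b-1/13a/2c	Duplication	Protostomes		Ancestral cluster may derive from a new hairpin masked by later loss
c19	2a-2/2a-1/2b-2	Duplication	Protostomes		Ancestral cluster may derive from a new hairpin masked by later loss
c20	92a/92b	Duplication	Metazoans		Duplications in insects and chordates may be independent
c21	100/let-7/125	Unknown	Metazoans		mir-100 and mir-125 are paralogs
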
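phylo_family	species
mir-4969	dme
mir-303	dme
mir-983	dme
mir-984	dme
mir-2499	dme
mir-4966	dme
mir-2498	dme
mir-991	dme
mir-992	dme
mir-982	dme,dsi,dps
mir-969	dme,dps
mir-287	dme,dsi,dps
mir-973	dme,dsi,dps
mir-974	dme,dsi,dps
mir-975	dme,dsi,dps
mir-976	dme,dsi,dps
mir-977	dme,dsi,dps
mir-978	dme,dsi,dps
mir-979	dme,dsi,dps
mir-960	dme,dsi,dps
mir-961	dme,dsi,dps
mir-962	dme,dsi,dps
mir-963	dme,dsi,dps
mir-964	dme,dsi,dps
mir-1002	dme,dsi,dps
mir-281	dme,dsi,dps
mir-310	dme,dsi,dps
mir-999	dme,dsi,dps,aga,tca
mir-972	dme,dsi,dps,tca
mir-959	dme,dsi,dps,aga,tca
mir-968	dme,dsi,dps,aga,tca
mir-6	dme,dsi,dps,aga,tca
mir-5	dme,dsi,dps,aga,tca
mir-4	dme,dsi,dps,aga,tca
mir-3	dme,dsi,dps,aga,tca
mir-309	dme,dsi,dps,aga,tca
mir-998	dme,dsi,dps,aga,tca
mir-994	dme,dsi,dps,aga,tca
mir-279	dme,dsi,dps,aga,tca
mir-9c	dme,dsi,dps,aga,tca
mir-306	dme,dsi,dps,aga,tca
mir-79	dme,dsi,dps,aga,tca
mir-9b	dme,dsi,dps,aga,tca
mir-286	dme,dsi,dps,aga,tca,cel,lgi
mir-11	dme,dsi,dps,aga,tca,cel,lgi
mir-318	dme,dsi,dps,aga,tca,cel,lgi
mir-304	dme,dsi,dps,aga,tca,cel,lgi
mir-12	dme,dsi,dps,aga,tca,lgi
mir-305	dme,dsi,dps,aga,tca,cel,lgi
mir-317	dme,dsi,dps,aga,tca,cel,lgi
mir-277	dme,dsi,dps,aga,tca,cel,lgi
mir-2	dme,dsi,dps,aga,tca,cel,lgi
mir-210	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-124	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-34	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-283	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-275	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-92	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-100	dme,dsi,dps,aga,tca,cel,lgi,hsa
let-7	dme,dsi,dps,aga,tca,cel,lgi,hsa
mir-125	dme,dsi,dps,aga,tca,cel,lgi,hsa
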
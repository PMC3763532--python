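((((dme:1.0,(dsi:0.5,dps:0.5)drosophila_relatives:0.5)Drosophila:1.0,(aga:1.5,tca:1.5)other_insects:0.5)Insects:1.0,(cel:2.5,lgi:2.5)lophotrochozoans:0.5)Protostomes:1.0,hsa:4.0)Metazoans;
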
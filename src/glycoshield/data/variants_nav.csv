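isoform,hgvs_p,phenotype,source,clinical_class
NaV1.1,S340F,Dravet syndrome,literature,pathogenic
NaV1.1,S340P,Dravet syndrome,literature,pathogenic
NaV1.1,S340Y,Dravet syndrome,ClinVar,pathogenic
NaV1.1,N1378H,Dravet syndrome,literature,pathogenic
NaV1.1,N1378T,Dravet syndrome,literature,pathogenic
NaV1.1,H1393P,Dravet syndrome,literature,pathogenic
NaV1.1,T1394I,Dravet syndrome,literature,pathogenic
NaV1.1,N1392fs,Dravet syndrome,literature,pathogenic
NaV1.1,H1393fs,Dravet syndrome,literature,pathogenic
NaV1.1,T1394fs,Dravet syndrome,literature,pathogenic
NaV1.5,T320N,Brugada syndrome,literature,pathogenic
NaV1.5,S1382I,Brugada syndrome,literature,pathogenic
NaV1.6,T1360N,Global developmental delay and seizures,literature,pathogenic
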
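isoform,asn_position,conservation,region,notes
NaV1.1,338,all,ECTL_I,homolog of NaV1.5 N291
NaV1.1,1378,all,ECTL_III,homolog of NaV1.5 N1365
NaV1.1,1392,all,ECTL_III,homolog of NaV1.5 N1380
NaV1.4,1191,all,ECTL_III,pore-proximal; homolog of NaV1.5 N1365
NaV1.4,1205,all,ECTL_III,membrane-parallel; homolog of NaV1.5 N1380
NaV1.5,291,all,ECTL_I,
NaV1.5,1365,all,ECTL_III,pore-proximal
NaV1.5,1380,all,ECTL_III,membrane-parallel
NaV1.5,328,shared_except_NaV1.7_NaV1.9,ECTL_I,sialic tip near DIV VSD
NaV1.5,1388,shared_NaV1.5_NaV1.7_NaV1.8,ECTL_III,points toward ECTL IV
NaV1.5,283,unique,ECTL_I,above DIII VSD
NaV1.5,288,unique,ECTL_I,
NaV1.5,318,unique,ECTL_I,above DIII VSD
NaV1.5,1374,unique,ECTL_III,above DII VSD
NaV1.6,1358,all,ECTL_III,homolog of NaV1.5 N1365
NaV1.8,819,unique,ECTL_II,clashes with beta2/beta4 Ig footprint
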
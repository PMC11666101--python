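lipid,upper_pct,inner_pct
DSM,21.0,10.0
POPC,35.0,15.0
DOPC,3.5,1.5
POPE,5.0,20.0
DOPE,2.0,5.0
POPS,0.0,15.0
POPI,0.0,5.0
POPA,2.2,0.0
CHOL,31.3,28.5
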
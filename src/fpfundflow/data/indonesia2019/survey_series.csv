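year,wra,pct_in_union,method,prevalence_pct
2017,72021000,71.90,tubal ligation,3.8
2017,72021000,71.90,pills,12.1
2017,72021000,71.90,IUD,4.7
2017,72021000,71.90,injectable,29
2017,72021000,71.90,condoms,2.5
2017,72021000,71.90,implant,4.7
2017,72021000,71.90,male sterilization,0.2
2017,72021000,71.90,other modern methods,6.6
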
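method,kind,units_per_cyp,cyp_per_procedure,unit_cost_public,unit_cost_private,source_public_pct,source_private_pct,currency
tubal ligation,permanent,,10.0,180.0,250.0,80,20,USD
pills,resupply,15.0,,0.6,1.2,30,70,USD
IUD,long-acting,,4.6,7.5,15.0,60,40,USD
injectable,resupply,4.0,,1.1,2.0,25,75,USD
condoms,resupply,120.0,,0.05,0.12,30,70,USD
implant,long-acting,,2.5,9.0,20.0,55,45,USD
male sterilization,permanent,,10.0,150.0,220.0,90,10,USD
other modern methods,resupply,1.0,,5.0,8.0,50,50,USD
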
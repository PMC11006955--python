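institution,from_stage,to_stage,amount,currency,note
BKKBN,origin,national,252736,USD_thousands,state budget allocation
BKKBN,national,provincial,225967,USD_thousands,
BKKBN,national,leakage,26769,USD_thousands,unexecuted budget and central operations
BKKBN,provincial,district,153009,USD_thousands,
BKKBN,provincial,leakage,72958,USD_thousands,unexecuted budget and provincial operations
BKKBN,district,expenditure_public,153009,USD_thousands,
BKKBN,district,expenditure_private,0,USD_thousands,explicit zero
Ministry of Health,origin,national,14160,USD_thousands,state budget allocation
Ministry of Health,national,provincial,14160,USD_thousands,
Ministry of Health,provincial,district,14160,USD_thousands,
Ministry of Health,district,expenditure_public,14160,USD_thousands,
Ministry of Health,district,expenditure_private,0,USD_thousands,explicit zero
Ministry of Finance,origin,national,185111,USD_thousands,special allocation and FP operational funds
Ministry of Finance,national,district,185111,USD_thousands,transferred directly to districts
Ministry of Finance,district,expenditure_public,185111,USD_thousands,
Ministry of Finance,district,expenditure_private,0,USD_thousands,explicit zero
Other ministries,origin,national,258,USD_thousands,
Other ministries,national,expenditure_public,258,USD_thousands,
Other ministries,national,expenditure_private,0,USD_thousands,explicit zero
JKN,origin,national,2616,USD_thousands,government premium subsidy earmarked for FP
JKN,national,district,2616,USD_thousands,
JKN,origin,district,26184,USD_thousands,top-up: premium revenue outside the national budget
JKN,district,expenditure_public,28198,USD_thousands,claims at public facilities
JKN,district,expenditure_private,602,USD_thousands,claims at contracted private facilities
UNFPA,origin,national,163,USD_thousands,donor funds channelled via government
UNFPA,national,expenditure_public,163,USD_thousands,
UNFPA,national,expenditure_private,0,USD_thousands,explicit zero
Other NGOs,origin,national,7259,USD_thousands,donor and NGO funds
Other NGOs,national,expenditure_public,0,USD_thousands,explicit zero
Other NGOs,national,expenditure_private,7260,USD_thousands,
Out-of-pocket Payment,origin,national,244413,USD_thousands,household payments at point of care
Out-of-pocket Payment,national,expenditure_public,49988,USD_thousands,paid at public facilities
Out-of-pocket Payment,national,expenditure_private,194425,USD_thousands,paid at private facilities
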
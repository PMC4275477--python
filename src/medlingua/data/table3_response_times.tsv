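query_fr	query_en	response_time_s	n_citations
Allaitement maternel	breast feeding	0.42	633
Angine	pharyngitis	0.53	845
AVC	stroke	0.54	1704
BPCO	COPD	0.49	1503
Cigarette électronique	electronic cigarette	0.42	24
Constipation	constipation	0.27	531
Coqueluche	whooping cough	0.54	314
Gale	scabies	0.57	148
Hémochromatose	hemochromatosis	0.59	712
Hypertension	hypertension	1.03	8694
Lupus	lupus	0.34	1147
Maladie cœliaque	celiac disease	0.58	723
Maladie de Crohn	Crohn disease	0.69	1363
Nutrition	nutrition	1.13	8367
Psychiatrie	psychiatry	0.94	5602
Sarcoïdose	sarcoidosis	0.77	1721
Scoliose	scoliosis	1.10	669
Soins infirmiers	nursing care	0.86	5767
Tabac	tobacco	0.42	679
Toxoplasmose	toxoplasmosis	0.74	1238
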
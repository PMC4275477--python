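query_en	babelmesh	multilingual_pubmed_french	pubmed	pubmed_tt
breast feeding	639	633	3	50
pharyngitis	2043	845	2326	82
stroke	2671	1704	202	52
COPD	687	1503	25	275
electronic cigarette	355	24	0	0
constipation	574	531	666	144
whooping cough	227	314	2	166
scabies	136	148	4	102
hemochromatosis	537	712	756	129
hypertension	10348	8694	12580	1533
lupus	2232	1147	2694	1150
celiac disease	649	723	2	305
Crohn disease	1190	1363	2	758
nutrition	4969	8367	6480	819
psychiatry	4453	5602	5394	1940
sarcoidosis	1522	1721	13	878
scoliosis	651	669	3	159
nursing care	14360	5767	2867	888
tobacco	1607	679	18	585
toxoplasmosis	1044	1238	10	701
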
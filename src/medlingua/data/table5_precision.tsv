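query_en	babelmesh_strict	babelmesh_relaxed	multilingual_pubmed_french_strict	multilingual_pubmed_french_relaxed	pubmed_lifo_strict	pubmed_lifo_relaxed	pubmed_relevance_strict	pubmed_relevance_relaxed	pubmed_tt_strict	pubmed_tt_relaxed
breast feeding	0.55	0.75	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00
pharyngitis	0.00	0.00	0.65	0.70	0.00	0.00	0.00	0.00	0.50	0.60
stroke	0.45	0.80	0.95	0.95	0.15	0.15	0.35	0.35	1.00	1.00
COPD	0.40	0.55	1.00	1.00	0.75	0.85	1.00	1.00	1.00	1.00
electronic cigarette	0.10	0.10	0.35	0.40	NA	NA	NA	NA	NA	NA
constipation	0.45	1.00	1.00	1.00	0.50	0.95	0.75	1.00	1.00	1.00
whooping cough	0.80	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00
scabies	0.90	1.00	1.00	1.00	0.25	0.25	0.25	0.25	1.00	1.00
hemochromatosis	0.65	0.95	1.00	1.00	0.70	1.00	0.85	1.00	1.00	1.00
hypertension	0.45	0.75	0.95	0.95	0.25	0.75	1.00	1.00	1.00	1.00
lupus	0.70	1.00	1.00	1.00	0.75	0.95	1.00	1.00	1.00	1.00
celiac disease	0.70	0.95	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00
Crohn disease	0.80	0.90	1.00	1.00	0.50	1.00	0.50	1.00	1.00	1.00
nutrition	0.45	0.70	0.70	1.00	0.25	0.60	1.00	1.00	1.00	1.00
psychiatry	0.75	0.80	1.00	1.00	0.85	0.95	0.90	0.95	1.00	1.00
sarcoidosis	0.70	0.90	1.00	1.00	0.92	0.92	0.92	0.92	1.00	1.00
scoliosis	0.65	0.90	1.00	1.00	0.67	0.67	0.67	0.67	1.00	1.00
nursing care	0.85	0.90	1.00	1.00	0.70	0.80	0.85	0.90	1.00	1.00
tobacco	0.60	0.90	1.00	1.00	0.83	0.89	0.83	0.89	1.00	1.00
toxoplasmosis	0.65	0.90	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00
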
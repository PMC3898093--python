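# Published over-representation results for a venous-thrombosis GWAS
# gene list after PPI network expansion and orthology mapping to mouse
# (34 mouse genes), tested against mouse phenotype annotation.
# Columns: rank, set size (K), overlap (k), p-value, BH q-value,
# phenotype set name.
rank	set_size	overlap	p_value	q_value	annotation
1	79	10	9.9.E-21	7.5.E-17	Abnormal blood coagulation
2	73	5	1.9.E-09	7.0.E-06	Increased bleeding time
3	37	4	1.3.E-08	3.4.E-05	Gastrointestinal hemorrhage
4	150	5	7.0.E-08	1.2.E-04	Increased leukocyte cell number
5	57	4	7.9.E-08	1.2.E-04	Abnormal cell adhesion
6	1258	9	1.5.E-07	1.9.E-04	Premature death
7	75	4	2.4.E-07	2.6.E-04	Decreased susceptibility to endotoxin shock
8	80	4	3.1.E-07	2.9.E-04	Thrombosis
9	94	4	6.0.E-07	5.0.E-04	Increased monocyte cell number
10	30	3	1.3.E-06	9.1.E-04	Abnormal cellular extravasation
11	277	5	1.4.E-06	9.1.E-04	Hemorrhage
12	3	2	1.5.E-06	9.1.E-04	Purpura
13	33	3	1.7.E-06	1.0.E-03	Decreased susceptibility to bacterial infection induced morbidity/mortality
14	153	4	4.1.E-06	2.1.E-03	Decreased erythrocyte cell number
15	153	4	4.1.E-06	2.1.E-03	Increased neutrophil cell number
16	50	3	6.1.E-06	2.9.E-03	Impaired macrophage chemotaxis
17	51	3	6.5.E-06	2.9.E-03	Decreased platelet aggregation
18	6	2	7.2.E-06	3.0.E-03	Abnormal circulating fibrinogen level
19	7	2	1.0.E-05	3.8.E-03	Uterine hemorrhage
20	7	2	1.0.E-05	3.8.E-03	Petechiae
21	60	3	1.1.E-05	3.8.E-03	Impaired neutrophil recruitment
22	8	2	1.4.E-05	4.4.E-03	Increased susceptibility to infection induced morbidity/mortality
23	65	3	1.4.E-05	4.4.E-03	Abnormal leukocyte migration
24	211	4	1.5.E-05	4.6.E-03	Increased sensitivity to induced morbidity/mortality
25	69	3	1.6.E-05	4.8.E-03	Increased eosinophil cell number
26	70	3	1.7.E-05	4.8.E-03	Abnormal myelopoiesis
27	9	2	1.7.E-05	4.8.E-03	Hemothorax
28	72	3	1.8.E-05	4.9.E-03	Abnormal cell migration
29	81	3	2.6.E-05	6.4.E-03	Internal hemorrhage
30	11	2	2.6.E-05	6.4.E-03	Skin hemorrhage
31	11	2	2.6.E-05	6.4.E-03	Abnormal platelet aggregation
32	86	3	3.1.E-05	7.3.E-03	Decreased angiogenesis
33	13	2	3.8.E-05	8.5.E-03	Decreased susceptibility to induced choroidal neovascularization
34	100	3	4.9.E-05	1.1.E-02	Abnormal inflammatory response
35	289	4	4.9.E-05	1.1.E-02	Anemia
36	15	2	5.0.E-05	1.1.E-02	Pulmonary alveolar hemorrhage
37	18	2	7.3.E-05	1.5.E-02	Abnormal uterine environment
38	20	2	9.1.E-05	1.8.E-02	Abnormal physiological neovascularization
39	21	2	1.0.E-04	1.9.E-02	Hemoperitoneum
40	22	2	1.1.E-04	2.0.E-02	Pregnancy-related premature death
41	22	2	1.1.E-04	2.0.E-02	Abnormal platelet activation
42	133	3	1.1.E-04	2.0.E-02	Decreased platelet cell number
43	24	2	1.3.E-04	2.3.E-02	Increased susceptibility to fungal infection
44	33	2	2.5.E-04	4.3.E-02	Decreased cerebral infarction size
45	180	3	2.7.E-04	4.6.E-02	Pallor
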
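# Published over-representation results for a venous-thrombosis GWAS
# gene list after PPI network expansion (43 human genes), tested against
# human phenotype annotation.  Columns: rank, set size (K), overlap (k),
# p-value, BH q-value, phenotype set name.
rank	set_size	overlap	p_value	q_value	annotation
1	5	4	9.3.E-12	4.9.E-09	Pregnancy loss, recurrent
2	12	4	9.1.E-10	2.4.E-07	Stroke
3	6	3	3.3.E-08	5.9.E-06	Stroke, ischemic
4	2	2	1.4.E-06	1.5.E-04	Fetal loss
5	2	2	1.4.E-06	1.5.E-04	Brain hemorrhage
6	4	2	8.6.E-06	7.6.E-04	Peripheral vascular disease
7	5	2	1.4.E-05	1.1.E-03	Polycystic ovary syndrome
8	7	2	3.0.E-05	2.0.E-03	Cerebrovascular disease
9	11	2	7.8.E-05	4.6.E-03	Myocardial infarction
10	12	2	9.3.E-05	5.0.E-03	Cardiovascular disease
11	25	2	4.2.E-04	2.0.E-02	Myocardial infarct
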
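# Published survey counts of annotation coverage across seven species:
# total inventory size, genes with any annotation, genes with phenotype
# annotation, genes connected in the species PPI network, and — for the
# six model organisms — how many human genes gain inferred phenotype /
# PPI annotation through orthologs in that species.
species	total_genes	all_annotated	phenotype_annotated	ppi_connected	phenotype_gain_to_human	ppi_gain_to_human
human	42059	34710	17198	9621	0	0
arabidopsis	33584	27274	0	6911	0	1814
worm	45727	18734	6513	2681	447	634
fly	22930	20106	16665	5622	848	1365
mouse	57992	48128	9966	1588	377	138
ecoli	4497	2531	0	47	0	0
yeast	6353	6303	5620	5479	583	1658
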
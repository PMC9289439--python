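family	snp	chromosome	gene	position	known_phenotype
leaf_wax	leaf_wax_1_51588525	1	001G269200	51588525	wax composition
leaf_wax	leaf_wax_1_51588838	1	001G269200	51588838	wax composition
leaf_wax	leaf_wax_1_51589143	1	001G269200	51589143	wax composition
leaf_wax	leaf_wax_1_51589435	1	001G269200	51589435	wax composition
dw	dw_6_42805319	6	006G067700	42805319	plant height and structure, stem and internode length
dw	dw_6_42804037	6	006G067700	42804037	plant height and structure, stem and internode length
d_locus	d_locus_6_50898459	6	006G147400	50898459	plant height and structure, sugar composition
d_locus	d_locus_6_50898536	6	006G147400	50898536	plant height and structure, sugar composition
d_locus	d_locus_6_50898315	6	006G147400	50898315	plant height and structure, sugar composition
d_locus	d_locus_6_50898231	6	006G147400	50898231	plant height and structure, sugar composition
d_locus	d_locus_6_50898523	6	006G147400	50898523	plant height and structure, sugar composition
d_locus	d_locus_6_50898525	6	006G147400	50898525	plant height and structure, sugar composition
ma	ma_6_40312463	6	006G057866	40312463	flowering time and maturity
ma	ma_6_2697734	6	006G004400	2697734	flowering time and maturity
tan	tan_9_57040680	9	009G229800	57040680	pigmentation and tannin production
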
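dimension	layer	parent_path	label	code	provenance
A	major		cardiovascular disease	01	stated
A	major		digestive system disease	02	stated
A	major		respiratory system disease	03	stated
A	major		urinary system disease	04	stated
A	major		reproductive system disease	05	stated
A	major		endocrine disease	06	stated
A	major		ophthalmology and otolaryngology disease	07	stated
A	major		oral disease	08	stated
A	major		bone disease	09	stated
A	major		skin disease	10	stated
A	major		nervous system disease	11	stated
A	major		blood system disease	12	stated
A	major		infectious disease	13	stated
A	major		tumor	14	stated
A	major		TCM viscera dialectics disease	15	stated
A	major		other diseases	16	stated
A	intermediate	cardiovascular disease	myocarditis	01	stated
A	intermediate	cardiovascular disease	pericarditis	02	stated
A	intermediate	cardiovascular disease	myocardial infarction	03	stated
A	intermediate	cardiovascular disease	arrhythmia	04	stated
A	intermediate	cardiovascular disease	myocardial ischemia	05	stated
A	intermediate	cardiovascular disease	arterial thrombosis	06	stated
A	intermediate	cardiovascular disease	hypertension	07	stated
A	intermediate	cardiovascular disease	atherosclerosis	08	stated
A	intermediate	respiratory system disease	SARS-CoV-2 infection	12	inferred
B	major		laboratory animal	11	stated
B	intermediate	laboratory animal	mouse	11	stated
B	intermediate	laboratory animal	rat	13	stated
B	intermediate	laboratory animal	guinea pig	15	stated
B	intermediate	laboratory animal	rabbit	27	inferred
B	minor	laboratory animal/mouse	BALB/c	001	stated
B	minor	laboratory animal/mouse	KM	002	stated
B	minor	laboratory animal/mouse	C57	003	stated
B	minor	laboratory animal/mouse	ICR-Tg(hACE2)	017	inferred
B	minor	laboratory animal/rat	SD	001	stated
B	minor	laboratory animal/rat	Wistar	002	stated
B	minor	laboratory animal/rabbit	New Zealand	001	stated
C	category		spontaneous	01	stated
C	category		induced	02	stated
C	category		genetic engineering	03	stated
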
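# Seed table for the EC -> SBO mapping store.
# Columns: ec_pattern, sbo_label, sbo_id, category, class_label
# Categories: one_to_one (a whole EC class/subclass/sub-subclass maps to one term),
# one_to_few (a handful of explicit EC numbers map to one term),
# one_to_many (a larger explicit subset of one sub-subclass maps to one term).
# Every (sbo_label, sbo_id) pair is asserted against the pinned miniature SBO
# ontology at load time. 18 distinct enzymatic-function classes.
ec_pattern	sbo_label	sbo_id	category	class_label
1.-.-.-	redox reaction	200	one_to_one	redox reaction
2.1.1.-	methylation	217	one_to_one	methylation
2.4.-.-	glycosylation	213	one_to_one	glycosylation
2.6.1.-	transamination	403	one_to_one	transamination
2.7.-.-	phosphorylation	214	one_to_one	phosphorylation
2.8.2.-	sulfation	219	one_to_one	sulfation
3.-.-.-	hydrolysis	376	one_to_one	hydrolysis
4.-.-.-	cleavage	178	one_to_one	cleavage
5.-.-.-	isomerisation	212	one_to_one	isomerisation
6.-.-.-	formation of a covalent bond	695	one_to_one	ligation
2.3.1.97	myristoylation	218	one_to_few	myristoylation
2.3.1.225	palmitoylation	224	one_to_few	palmitoylation
2.3.2.27	ubiquitination	216	one_to_few	ubiquitination
2.5.1.58	farnesylation	223	one_to_few	farnesylation
2.5.1.59	geranylation	222	one_to_few	geranylation
2.3.1.1	acetylation	215	one_to_many	acetylation
2.3.1.5	acetylation	215	one_to_many	acetylation
2.3.1.6	acetylation	215	one_to_many	acetylation
2.3.1.9	acetylation	215	one_to_many	acetylation
2.3.1.12	acetylation	215	one_to_many	acetylation
2.5.1.29	prenylation	220	one_to_many	prenylation
2.5.1.41	prenylation	220	one_to_many	prenylation
2.5.1.60	prenylation	220	one_to_many	prenylation
1.14.11.1	hydroxylation	233	one_to_many	hydroxylation
1.14.13.9	hydroxylation	233	one_to_many	hydroxylation
1.14.18.1	hydroxylation	233	one_to_many	hydroxylation
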
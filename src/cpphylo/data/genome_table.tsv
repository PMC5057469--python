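family	species	accession	group	genome_length	gc_percent	protein_genes	orfs	trna	tmrna	rrna	ncrna	introns
Scinaiaceae	Nothogenia fastigiata	SAMEA4358435	ingroup	182457	33.0	193	8	30	1	3	1	2
Scinaiaceae	Scinaia undulata	SAMEA4478602	ingroup	183795	35.9	197	9	31	1	3	1	2
Galaxauraceae	Actinotrichia fragilis	SAMEA4357171	ingroup	183324	29.8	197	9	31	1	3	1	2
Galaxauraceae	Galaxaura rugosa	SAMEA4357173	ingroup	181215	29.6	197	7	31	1	3	1	2
Galaxauraceae	Tricleocarpa cylindrica	SAMEA4478608	ingroup	>=150119	-	>=149	>=8	>=25	>=1	>=1	>=1	>=0
Galaxauraceae	Dichotomaria marginata	SAMEA4357172	ingroup	184395	28.8	197	11	31	1	3	1	2
Liagoraceae	Liagora brachyclada	SAMEA4395348	ingroup	182937	33.7	195	9	31	1	3	1	2
Liagoraceae	Liagora harveyana	SAMEA4358432	ingroup	182933	33.9	195	10	31	1	3	1	2
Liagoraceae	Izziella formosana	SAMEA4358392	ingroup	183248	35.0	195	9	31	1	3	1	2
Liagoraceae	Neoizziella asiatica	SAMEA4358434	ingroup	183313	33.4	195	10	31	1	3	1	2
Liagoraceae	Titanophycus setchellii	SAMEA4478603	ingroup	>=183356	-	195	>=9	>=31	>=1	>=3	>=1	>=2
Liagoraceae	Helminthora furcellata	SAMEA4393237	ingroup	184585	32.1	195	8	31	1	3	1	2
Liagoraceae	Trichogloeopsis pedicellata	SAMEA4358437	ingroup	183497	31.9	194	8	31	1	3	1	2
Liagoraceae	Hommersandiophycus borowitzkae	SAMEA4358391	ingroup	184728	32.2	194	9	31	1	3	1	2
Liagoraceae	Dermonema virens	SAMEA4357169	ingroup	184997	34.1	195	9	31	1	3	1	2
Liagoraceae	Helminthocladia australis	SAMEA4358292	ingroup	185694	32.8	195	9	31	1	3	1	2
Yamadaellaceae	Yamadaella caenomyce	SAMEA4358436	ingroup	182460	35.9	194	9	31	1	3	1	2
Liagoropsidaceae	Liagoropsis maxima	SAMEA4358433	ingroup	189564	32.1	195	11	31	1	3	1	2
Nemaliaceae	Nemalion sp.	SAMEA4478604	ingroup	182930	35.5	194	7	31	1	3	1	2
Palmariaceae	Palmaria palmata	SAMEA4478605	outgroup	>=187103	-	>=196	>=11	>=31	>=1	>=3	>=1	>=2
Rhodothamniellaceae	Rhodothamniella floridula	SAMEA4478606	outgroup	>=182494	-	>=196	>=9	>=29	>=1	>=1	>=1	>=2
Acrochaetiaceae	Acrochaetium secundatum	SAMEA4393238	outgroup	>=183541	-	>=196	>=12	>=29	>=1	>=0	>=1	>=2
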
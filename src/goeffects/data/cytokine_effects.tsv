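# Nine-cytokine benchmark: qualitative effects of each cytokine gene on
# eight immunological hypothesis terms.  Source column G holds the
# tool-derived calls, M the calls of a domain expert (immunologist) working
# from the literature.  Cells with both a positive and a negative call are
# written 1/-1; absent pairs mean no effect was determined.
# gene	hypothesis	source	value
IL-2	TH2	G	1/-1
IL-2	Antigen Presentation	M	0
IL-2	Chemotaxis	G	1
IL-2	Metastasis	G	1
IL-2	Angiogenesis	G	1/-1
IL-2	T Cell Activation	G	1/-1
IL-2	T Cell Activation	M	1
IL-2	Cell Proliferation	G	1
IL-2	Cell Proliferation	M	1
IL-2	Apoptosis	G	1/-1
IL-2	Apoptosis	M	-1
IL-4	TH2	G	1/-1
IL-4	TH2	M	1
IL-4	Antigen Presentation	M	1
IL-4	Chemotaxis	G	1
IL-4	Chemotaxis	M	1
IL-4	Angiogenesis	G	1/-1
IL-4	Cell Proliferation	G	1
IL-4	Cell Proliferation	M	1
IL-4	Apoptosis	G	-1
IL-4	Apoptosis	M	0
IL-6	TH2	G	1
IL-6	Antigen Presentation	M	0
IL-6	Chemotaxis	G	1
IL-6	Chemotaxis	M	-1
IL-6	Metastasis	G	1
IL-6	Metastasis	M	0
IL-6	Angiogenesis	G	1
IL-6	T Cell Activation	G	1
IL-6	Cell Proliferation	G	1/-1
IL-6	Cell Proliferation	M	0
IL-6	Apoptosis	G	1/-1
IL-8	Chemotaxis	G	1
IL-8	Chemotaxis	M	1
IL-8	Metastasis	G	1
IL-8	Metastasis	M	1
IL-8	Angiogenesis	G	1
IL-8	Angiogenesis	M	1
IL-8	Cell Proliferation	G	-1
IL-8	Cell Proliferation	M	-1
IL-8	Apoptosis	G	1
IL-10	TH2	G	1
IL-10	TH2	M	1
IL-10	Antigen Presentation	M	1
IL-10	Chemotaxis	G	1
IL-10	Metastasis	G	1
IL-10	Metastasis	M	0
IL-10	T Cell Activation	G	-1
IL-10	Cell Proliferation	G	-1
IL-10	Cell Proliferation	M	-1
IL-10	Apoptosis	G	1/-1
IL-10	Apoptosis	M	-1
IL-13	TH2	M	1
IL-13	Cell Proliferation	G	1
IL-13	Cell Proliferation	M	0
IL-18	TH2	G	1
IL-18	TH2	M	1
IL-18	Metastasis	M	1
IL-18	Angiogenesis	G	1
IL-18	Angiogenesis	M	1
IL-18	T Cell Activation	G	1
IL-18	Cell Proliferation	G	1
IL-18	Cell Proliferation	M	1
IL-18	Apoptosis	G	1
IL-18	Apoptosis	M	1
IFNg	TH2	M	-1
IFNg	Antigen Presentation	G	-1
IFNg	Antigen Presentation	M	1
IFNg	Chemotaxis	G	1
IFNg	Metastasis	G	1
IFNg	T Cell Activation	G	1
IFNg	Cell Proliferation	G	1/-1
IFNg	Cell Proliferation	M	-1
IFNg	Apoptosis	G	1
IFNg	Apoptosis	M	1
TGFb	TH2	M	1
TGFb	Chemotaxis	G	1
TGFb	Metastasis	G	1
TGFb	Angiogenesis	G	1/-1
TGFb	Cell Proliferation	G	-1
TGFb	Cell Proliferation	M	1
TGFb	Apoptosis	G	1/-1
TGFb	Apoptosis	M	-1
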
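!gaf-version: 2.2
TOY	CASP3	CASP3	involved_in	GO:0043065	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	CASP3	CASP3	involved_in	GO:0006915	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	BCL2	BCL2	involved_in	GO:0043066	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	BCL2	BCL2	involved_in	GO:0006916	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	BCL2	BCL2	involved_in	GO:0043066	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	IL10	IL10	involved_in	GO:0042981	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	IL10	IL10	involved_in	GO:0006916	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	TP53	TP53	involved_in	GO:0043065	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	TP53	TP53	involved_in	GO:0006915	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
TOY	TP53	TP53	involved_in	GO:0043065	TOY:0000001	IEA		P			protein	taxon:9606	20200101	toy		
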
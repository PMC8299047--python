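FDA_PLASMA_MARKERS	curated stand-in panel of FDA-cleared plasma protein marker genes (editable fixture)	ALB	AFP	APOA1	APOB	B2M	CEACAM5	CGA	CRP	ERBB2	F2	FGA	FGB	FGG	HP	IGFBP3	KLK3	LGALS3BP	LPA	MB	MUC16	PLG	SERPINA1	SERPINC1	SHBG	TF	TG	TNNI3	TNNT2	TTR	VWF
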
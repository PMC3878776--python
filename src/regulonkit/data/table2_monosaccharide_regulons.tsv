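regulator_name	locus_tag	n_orthologs	pathway	family
AraR	BT0354	8	Arabinose, arabinan	NrtR
Crp	BT4338	11	Multiple sugars	Crp
FucR	BT1272	7	Fucose	GntR
KdgR	BT0487	10	Glucuronate, galacturonate	LacI
ManR	BT2103	3	Mannose, mannosides	GntR
NanR	BT0433	11	Sialic acid; N-acetylglucosamine	ROK
RhaR	BT3768	8	Rhamnose	AraC
UxaR	BT0824	6	Glucuronate, galacturonate	LacI
UxmR	BT3613	6	Mannuronate	LacI
UxuR	BT1434	3	Glucuronate	LacI
XylR	BT0791	10	Xylose	NrtR
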
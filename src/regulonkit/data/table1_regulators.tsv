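locus_tag	class	regulon_name	n_orthologs	substrate
BT0138	HTCS		4
BT0267	HTCS	HTCS_Aga-1	1	Arabinogalactans
BT0366	HTCS	HTCS_Ara-1	6	Arabinans
BT0958	HTCS		2
BT0981	HTCS		6	Rhamnogalacturonans
BT1635	HTCS		2	N-Acetylglucosamine polymers
BT1734	HTCS		7
BT1754	HTCS	HTCS_Fru	10	Fructosides
BT2391	HTCS		1
BT2628	HTCS	HTCS_Man-1	3	Mannans
BT2826	HTCS	HTCS_Ogl-1	1	O-glycans
BT2860	HTCS		1
BT2897	HTCS		5	Arabinans
BT2923	HTCS		4
BT2971	HTCS		1	N-Acetylglucosamine polymers
BT3049	HTCS	HTCS_Ara-2	6	Arabinans
BT3097	HTCS		2	Arabinans
BT3134	HTCS		3	N-Acetylglucosamine polymers
BT3172	HTCS		2	Mannans
BT3302	HTCS	HTCS_Man-2	1	Mannans
BT3334	HTCS	HTCS_Hya	7	Chondroitin sulfate, Hyaluronan
BT3465	HTCS		3
BT3678	HTCS		1	Arabinans
BT3738	HTCS		3
BT3786	HTCS	HTCS_Man-3	4	Mannans
BT3800	HTCS		3	N-Acetylglucosamine polymers
BT3951	HTCS		3
BT3957	HTCS		3	Mannans
BT4111	HTCS	HTCS_Rgu-1	8	Rhamnogalacturonans
BT4124	HTCS	HTCS_Rgu-1	2	Rhamnogalacturonans
BT4137	HTCS	HTCS_Ogl-2	1	O-glycans
BT4178	HTCS	HTCS_Rgu-2	3	Rhamnogalacturonans
BT4182	HTCS	HTCS_Rgu-2	2	Rhamnogalacturonans
BT4236	HTCS		2
BT4663	HTCS	HTCS_Hep	4	Heparin
BT4673	HTCS	HTCS_Pga	3	Pectic galactan
BT2160	SusR_like	SusR4	2
BT3091	SusR_like	SusR2	5	Dextran
BT3309	SusR_like	SusR3	2
BT3705	SusR_like	SusR	6	Starch
BT4069	SusR_like		2
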
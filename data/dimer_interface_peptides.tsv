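isoform	sequence	range_label
trans	KAEPSLKEQILEHESLGLLR	1696-1717
trans	DATACYDR	1716-1725
trans	AIQLEPDQIIHYHGVVK	1724-1742
trans	SMLGLGQLSTVITQVNGVHANR	1741-1764
trans	AGHHQTAYNALLNAGESR	1933-1952
trans	AKWLWSK	1958-1967
trans	GDVHQALIVLQK	1966-1979
trans	GVELCFPENETPPEGkNMLIHGR	1978-2002
trans	AMLLVGR	2001-2009
trans	FMEETANFESNAIMK	2008-2024
trans	YKDVTACLPEWEDGHFYLAK	2023-2044
trans	YYDKLMPMVTDNK	2043-2057
trans	LQGVIkTR	2598-2607
cis	KAEPSLKEQILEHESLGLLR	1696-1717
cis	DATACYDR	1716-1725
cis	AIQLEPDQIIHYHGVVK	1724-1742
cis	SMLGLGQLSTVITQVNGVHANR	1741-1764
cis	AGHHQTAYNALLNAGESR	1933-1952
cis	AKWLWSK	1958-1967
cis	GDVHQALIVLQK	1966-1979
cis	GVELCFPENETPPEGK	1978-1995
cis	NMLIHGR	1994-2002
cis	AMLLVGR	2001-2009
cis	FMEETANFESNAIMK	2008-2024
cis	YKDVTACLPEWEDGHFYLAK	2023-2044
cis	YYDKLMPMVTDNK	2043-2057
cis	LQGVIkTR	2598-2607
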
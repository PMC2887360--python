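family	pfam_csv	cog_csv	priority
PP2C	PF00481	COG0631	0
SPOIIE	PF07228	COG2208	1
PPP_CANDIDATE	PF00149	COG0639	2
PTP		COG2453	3
LOW_MW_PTP		COG0394	4
DSP_PTP		COG2365	5
PTP_OTHER		COG4551	6
PTP_OTHER		COG5350	7
PTPZ		COG4464	8
ELK		COG0515	9
NON_ELK_KINASE		COG2172	10
ANTI_ANTI_SIGMA		COG1366	11
RHODANESE		COG0607	12
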
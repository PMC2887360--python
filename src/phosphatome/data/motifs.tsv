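name	pattern	family	source
GDXHG	GDXHG	PPP	PPP signature motif 1
GDXXDRG	GDXXDRG	PPP	PPP signature motif 2
GNHE	GNHE	PPP	PPP signature motif 3
ILV_DST_G	(I/L/V)D(S/T)G	PPP	distinguishes PPP-like from ApaH-like
CDC25	CE[F/Y]SXXR	CDC25	Cdc25 active-site motif on rhodanese fold
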
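# Acid dissociation constants at 298.15 K (CRC Handbook values); used for
# Henderson-Hasselbalch anion fractions of the volatile fatty acids.
name	pka	source
acetate	4.76	CRC
propionate	4.87	CRC
formate	3.75	CRC
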
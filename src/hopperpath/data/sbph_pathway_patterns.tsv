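pathway	S6_S0	R6_R0	R0_S0	R6_S6
Betanidin degradation		down		lower
Cytokinins degradation		down		lower
Glutamate degradation III		down		lower
IAA conjugate biosynthesis I		up		higher
IAA conjugate biosynthesis II		up		higher
Spermine biosynthesis		up		higher
Very long chain fatty acid biosynthesis		up		higher
Momilactone biosynthesis		up		higher
Flavonoid biosynthesis		down	higher	higher
Mixed acid fermentation		down	higher	higher
Pinobanksin biosynthesis		down	higher	higher
Aminopropanol biosynthesis		down	lower	lower
Salicylate biosynthesis		down	lower	lower
Serine biosynthesis		down	lower	lower
Threonine degradation II		down	lower	lower
Threonine degradation III (to methylglyoxal)		down	lower	lower
Reductive TCA cycle I		up	higher	higher
13-LOX and 13-HPL pathway		up	lower	lower
Divinyl ether biosynthesis II (13-LOX)		up	lower	lower
Ureide biosynthesis	up	down	lower	lower
phenylalanine degradation III	up	down		lower
methylerythritol phosphate pathway	down		lower	lower
thiamine biosynthesis	down		lower	lower
lysine degradation I	up		higher	higher
phospholipid biosynthesis II	up		lower	lower
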
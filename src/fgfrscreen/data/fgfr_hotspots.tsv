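gene	codon	note
FGFR1	546	N546K, kinase domain
FGFR1	656	K656E/D, activation loop
FGFR2	252	S252W, Ig2-Ig3 linker
FGFR2	253	P253R, Ig2-Ig3 linker
FGFR2	549	N549K, kinase domain
FGFR2	659	K659E/N, activation loop
FGFR3	248	R248C, Ig2-Ig3 linker
FGFR3	249	S249C, Ig2-Ig3 linker
FGFR3	370	G370C, extracellular juxtamembrane
FGFR3	371	S371C, extracellular juxtamembrane
FGFR3	373	Y373C, extracellular juxtamembrane
FGFR3	380	G380R, transmembrane domain
FGFR3	650	K650E/M, activation loop
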
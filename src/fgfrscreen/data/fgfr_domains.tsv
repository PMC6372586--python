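gene	domain	aa_start	aa_end
FGFR1	Ig1	25	119
FGFR1	acid_box	120	138
FGFR1	Ig2	158	246
FGFR1	Ig3	255	357
FGFR1	TMD	377	397
FGFR1	TKD	478	767
FGFR2	Ig1	25	125
FGFR2	acid_box	126	137
FGFR2	Ig2	154	247
FGFR2	Ig3	256	358
FGFR2	TMD	378	398
FGFR2	TKD	481	770
FGFR3	Ig1	25	124
FGFR3	acid_box	126	137
FGFR3	Ig2	151	241
FGFR3	Ig3	249	349
FGFR3	TMD	370	396
FGFR3	TKD	472	761
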
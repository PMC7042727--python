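AD1	100	0	0	1	2
AD1	101	0	0	2	0
AD1	102	100	101	1	2
AD1	103	0	0	2	0
AD1	121	100	101	2	2
AD1	122	100	101	2	1
AD1	123	100	101	1	1
AD1	124	100	101	1	2
AD1	200	102	103	1	2
AD1	203	0	0	2	0
AD1	126	0	0	1	0
AD1	201	200	203	2	1
AD1	202	200	203	1	1
AD1	221	126	122	1	1
AD1	222	126	122	2	1
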
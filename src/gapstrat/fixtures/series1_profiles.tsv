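tumor_id	bands
G94	7p11.2,7p12.1
G55	7p11.2
G91	7p11.2
G80	7p11.2
G72	7p11.2
G68	7p11.2
G67	7p11.2
G56	7p11.2
G44	7p11.2
G40	7p11.2
G37	7p11.2
G30	7p11.2
GBM3	7p11.2
GBM7	7p11.2
GBM11	7p11.2
GBM12	7p11.2
GBM17	7p11.2
G73	4q11,4q12,4q13.3
G12	4q11,4q12
GBM1	4q12
GBM14	4q12
G51	12q13.3,12q14.1
G46	12q14.1,12q14.3,12q15
G25	12q14.1
G79	1q32.1
G54	1q32.1
G10	16q12.1,16q12.2
G39	7p11.2,12q13.3,12q14.1
G41	7p11.2,12q14.1,12q15
G53	7p11.2,7p21.3,7p22.1,12q15
G70	7p11.2,12q13.3,12q14.1
G83	1q32.1,7p11.2
G65	1q32.1,7p11.2
GBM19	7p21.1,7p12.3,7p11.2,7q22.3
G23	1q32.1,7p11.2,12q13.3,12q14.1
G82	4q12,4q13.3,7p11.2,12q13.12,12q13.13,12q13.3,12q14.1,12q15
G90	5q34,6q25,7p11.2
G81	7p11.2,17p13.1,17q25.1
G71	7p11.2,11p13
GBM4	7p11.2,7p12.1,11p15.3,11p11.2,11q13.3,11q25,12q13.3,12q14.1
GBM13	4q12,12q14.1
GBM22	4q12,12q13.3,12q14.1
G8	1p12,1p13,1p21,7q21.2,7q21.3
G88	4q12,4q13.3,7q31.2,12q13.3,12q14.1,12q15,12q21.1
G89	1p36.21,12q13.3,12q14.1,17q11.2,17q12,17q21,17q22,17q24
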
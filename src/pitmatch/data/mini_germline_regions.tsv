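allele	region	start	end
TRAV1-2*01	FR1	1	75
TRAV1-2*01	CDR1	76	93
TRAV1-2*01	FR2	94	144
TRAV1-2*01	CDR2	145	159
TRAV1-2*01	FR3	160	198
TRAV5*01	FR1	1	75
TRAV5*01	CDR1	76	93
TRAV5*01	FR2	94	144
TRAV5*01	CDR2	145	165
TRAV5*01	FR3	166	204
TRAV8-2*01	FR1	1	75
TRAV8-2*01	CDR1	76	96
TRAV8-2*01	FR2	97	147
TRAV8-2*01	CDR2	148	171
TRAV8-2*01	FR3	172	210
TRAV12-2*01	FR1	1	75
TRAV12-2*01	CDR1	76	90
TRAV12-2*01	FR2	91	141
TRAV12-2*01	CDR2	142	156
TRAV12-2*01	FR3	157	195
TRAV13-1*01	FR1	1	75
TRAV13-1*01	CDR1	76	93
TRAV13-1*01	FR2	94	144
TRAV13-1*01	CDR2	145	162
TRAV13-1*01	FR3	163	201
TRAV26-2*01	FR1	1	75
TRAV26-2*01	CDR1	76	96
TRAV26-2*01	FR2	97	147
TRAV26-2*01	CDR2	148	168
TRAV26-2*01	FR3	169	207
TRAV4*01	FR1	1	75
TRAV4*01	CDR1	76	96
TRAV4*01	FR2	97	147
TRAV4*01	CDR2	148	171
TRAV4*01	FR3	172	210
TRAV41*01	FR1	1	75
TRAV41*01	CDR1	76	93
TRAV41*01	FR2	94	144
TRAV41*01	CDR2	145	159
TRAV41*01	FR3	160	198
TRAJ8*01	FR4	28	57
TRAJ15*01	FR4	28	57
TRAJ36*01	FR4	28	57
TRAJ44*01	FR4	28	57
TRAJ49*01	FR4	28	57
TRAJ53*01	FR4	28	57
TRBJ1-1*01	FR4	28	57
TRBJ1-2*01	FR4	28	57
TRBJ2-1*01	FR4	28	57
TRBJ2-3*01	FR4	28	57
TRBJ2-5*01	FR4	28	57
TRBJ2-7*01	FR4	28	57
TRBV5-1*01	FR1	1	75
TRBV5-1*01	CDR1	76	90
TRBV5-1*01	FR2	91	141
TRBV5-1*01	CDR2	142	159
TRBV5-1*01	FR3	160	198
TRBV7-2*01	FR1	1	75
TRBV7-2*01	CDR1	76	90
TRBV7-2*01	FR2	91	141
TRBV7-2*01	CDR2	142	159
TRBV7-2*01	FR3	160	198
TRBV9*01	FR1	1	75
TRBV9*01	CDR1	76	90
TRBV9*01	FR2	91	141
TRBV9*01	CDR2	142	159
TRBV9*01	FR3	160	198
TRBV12-4*01	FR1	1	75
TRBV12-4*01	CDR1	76	90
TRBV12-4*01	FR2	91	141
TRBV12-4*01	CDR2	142	159
TRBV12-4*01	FR3	160	198
TRBV19*01	FR1	1	75
TRBV19*01	CDR1	76	90
TRBV19*01	FR2	91	141
TRBV19*01	CDR2	142	159
TRBV19*01	FR3	160	198
TRBV28*01	FR1	1	75
TRBV28*01	CDR1	76	90
TRBV28*01	FR2	91	141
TRBV28*01	CDR2	142	159
TRBV28*01	FR3	160	198
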
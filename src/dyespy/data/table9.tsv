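esid	n_spectra	phase1_pred	phase1_true	phase2_pred	phase2_true	phase3_pred	phase3_true
D1	50	oxidative (82%)	oxidative	A+KK+NN (64%)	A+KK (18%)	no color match (78%)	dark blue (0%)
D2	50	nonoxidative (100%)	oxidative	CX (100%)	D+AA+DD+FF+PP	no color match (100%)	yellow brown
D3	50	oxidative (62%)	oxidative	IC	C+D+E+DD+HH+PP (8%)	no color match (100%)	red brown
D4	50	oxidative (100%)	oxidative	D+E+RR (100%)	D+E+RR	no color match (100%)	purple
D5	50	nonoxidative (100%)	oxidative	AX	E+TT	no color match (100%)	dark red
D7	50	oxidative (100%)	oxidative	D+E+AA+FF+PP (60%)	D+E+AA+FF+PP	black (60%)	black
D9	50	nonoxidative (100%)	oxidative	AX+GX (98%)	C+D+E+DD+HH+PP	red brown (98%)	red brown
D10	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (100%)	LL+AX+DX+FX+GX	black (80%)	brown (20%)
D11	50	nonoxidative (100%)	nonoxidative	JX (82%)	LL+CX+KX+JX	pink (100%)	pink
D14	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (78%)	AX+DX+FX+GX	brown (100%)	black
D15	50	oxidative (100%)	oxidative	IC	D+AA+DD+FF+NN+OO+UU (0%)	no color match (70%)	brown
D16	50	nonoxidative (100%)	oxidative	No Match (62%)	D+DD+GG+NN+OO+QQ (0%)	no color match (100%)	red brown
D17	50	oxidative (100%)	oxidative	D+E+AA+FF+PP (68%)	D+AA+OO+PP+TT	IC	black (48%)
D18	50	oxidative (100%)	oxidative	D+DD+GG+NN+OO+QQ (74%)	D+AA+FF+TT (18%)	no color match (68%)	brown (16%)
D19	50	nonoxidative (90%)	oxidative (10%)	No Match (84%)	D+FF+OO+QQ+TT (0%)	no color match (100%)	brown
D20	50	oxidative (100%)	oxidative	D+AA+OO+PP+TT (52%)	D+DD+UU (0%)	black (68%)	black
D21	50	oxidative (100%)	oxidative	B+AA+DD+OO+PP+JJ (72%)	A+B+C+DD+FF+NN+OO (0%)	no color match (52%)	red brown
D22	50	oxidative (100%)	oxidative	B+C+AA+DD (96%)	A+AA+BB+DD+NN	no color match (100%)	black
D23	50	oxidative (80%)	oxidative	B+C+AA+DD (80%)	A+B+C+AA+DD+FF+NN	light brown (92%)	light brown
D24	50	nonoxidative (74%)	oxidative (26%)	No Match (60%)	B+AA+DD+OO+PP+JJ (14%)	dark purple (54%)	dark purple
D25	50	oxidative (100%)	oxidative	D+AA+OO+PP+TT (76%)	A+D+AA+DD+OO+PP (24%)	black (76%)	dark blue (24%)
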
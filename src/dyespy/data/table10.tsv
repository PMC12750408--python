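esid	weeks	n_spectra	phase1_pred	phase1_true	phase2_pred	phase2_true	phase3_pred	phase3_true
D1	0	50	oxidative (100%)	oxidative	A+KK (100%)	A+KK	no color match (100%)	dark blue
D1	1	50	oxidative (100%)	oxidative	A+KK (100%)	A+KK	no color match (100%)	dark blue
D1	2	50	oxidative (100%)	oxidative	A+KK (60%)	A+KK	no color match (100%)	dark blue
D1	3	50	oxidative (78%)	oxidative	A+KK (78%)	A+KK	no color match (100%)	dark blue
D1	4	50	oxidative (100%)	oxidative	A+KK (100%)	A+KK	No Color Match (100%)	dark blue
D1	5	50	oxidative (100%)	oxidative	A+KK (74%)	A+KK	no color match (100%)	dark blue
D1	6	50	oxidative (100%)	oxidative	E+TT (66%)	A+KK (34%)	no color match (100%)	dark blue
D1	7	50	oxidative (100%)	oxidative	A+KK (68%)	A+KK	no color match (100%)	dark blue
D7	0	50	oxidative (100%)	oxidative	D+E+AA+FF+PP (52%)	D+E+AA+FF+PP	IC	black (20%)
D7	1	50	oxidative (100%)	oxidative	IC	D+E+AA+FF+PP (0%)	IC	black (32%)
D7	2	50	oxidative (100%)	oxidative	D+AA+OO+PP+TT (70%)	D+E+AA+FF+PP (0%)	no color match (100%)	black
D7	3	50	oxidative (100%)	oxidative	A+D+AA+DD+OO+PP (72%)	D+E+AA+FF+PP (0%)	dark blue (100%)	black
D7	4	50	oxidative (100%)	oxidative	A+E+DD+FF+HH (64%)	D+E+AA+FF+PP (0%)	no color match (94%)	black (0%)
D7	5	50	oxidative (100%)	oxidative	A+D+AA+DD+OO+PP (100%)	D+E+AA+FF+PP	dark blue (100%)	black
D7	6	50	oxidative (100%)	oxidative	E+TT (74%)	D+E+AA+FF+PP (0%)	no color match (96%)	black (0%)
D7	7	50	oxidative (100%)	oxidative	E+TT (98%)	D+E+AA+FF+PP (0%)	no color match (100%)	black
D14	0	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (80%)	AX+DX+FX+GX	brown (80%)	black (20%)
D14	1	50	nonoxidative (100%)	nonoxidative	AX+FX+GX (62%)	AX+DX+FX+GX (38%)	brown (100%)	black
D14	2	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (100%)	AX+DX+FX+GX	brown (100%)	black
D14	3	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (54%)	AX+DX+FX+GX	brown (80%)	black (20%)
D14	4	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (98%)	AX+DX+FX+GX	No Color Match (68%)	black (0%)
D14	5	50	nonoxidative (100%)	nonoxidative	FX (56%)	AX+DX+FX+GX (38%)	brown (74%)	black (0%)
D14	6	50	nonoxidative (100%)	nonoxidative	AX+DX+FX+GX (52%)	AX+DX+FX+GX	no color match (60%)	black (0%)
D14	7	50	nonoxidative (82%)	nonoxidative	DX+FX (54%)	AX+DX+FX+GX (6%)	no color match (100%)	black
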
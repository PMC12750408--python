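esid	n_spectra	true_mixture	pred_mixture	proportion_pct	subset_recall_pct
hD1	12	A+KK	A+KK	100	100
hD2, hD33	24	D+AA+DD+FF+PP	D+AA+DD+FF+PP	100	100
hD3, hD9	24	C+D+E+DD+HH+PP	C+D+E+DD+HH+PP	100	100
hD4	12	D+E+RR	D+E+RR	100	100
hD5	12	E+TT	E+TT	100	100
hD6	12	A+KK+NN	A+KK+NN	100	100
hD7	12	D+E+AA+FF+PP	D+E+AA+FF+PP	100	100
hD8	12	D+PP	D+PP	100	100
hD15	12	D+AA+DD+FF+NN+OO+UU	D+AA+DD+FF+NN+OO+UU	100	100
hD16	12	D+DD+GG+NN+OO+QQ	D+DD+GG+NN+OO+QQ	100	100
hD17	12	D+AA+OO+PP+TT	D+AA+OO+PP+TT	100	100
hD18	12	D+AA+FF+TT	D+AA+FF+TT	100	100
hD19	12	D+FF+OO+QQ+TT	D+FF+OO+QQ+TT	100	100
hD20	12	D+DD+UU	D+DD+UU	100	100
hD21	12	A+B+C+DD+FF+NN+OO	A+B+C+DD+FF+NN+OO	100	100
hD22	12	A+AA+BB+DD+NN	A+AA+BB+DD+NN	100	100
hD23	12	A+B+C+AA+DD+FF+NN	A+B+C+AA+DD+FF+NN	100	100
hD24	12	B+AA+DD+OO+PP+JJ	B+AA+DD+OO+PP+JJ	100	100
hD25	12	A+D+AA+DD+OO+PP	A+D+AA+DD+OO+PP	100	100
hD26	12	A+DD+HH	A+DD+HH	100	100
hD27	12	A+DD+FF+HH	A+DD+FF+HH	100	100
hD28	12	A+E+DD+FF+HH	A+E+DD+FF+HH	100	100
hD29	12	D+AA+DD+OO+PP	D+AA+DD+OO+PP	100	100
hD30	12	D+DD+FF+GG+OO+QQ	D+DD+FF+GG+OO+QQ	100	100
hD31	12	D+AA+DD+FF+OO+QQ	D+AA+DD+FF+OO+QQ	100	100
hD32	12	D+AA+DD+FF+OO	D+AA+DD+FF+OO	100	100
hD34	12	C+D+DD+OO+PP+IP	C+D+DD+OO+PP+IP	100	100
hD35	12	C+D+DD+HH+IP	C+D+DD+HH+IP	100	100
hD36, hD38	24	D+E+AA+OO+IP	D+E+AA+OO+IP	100	100
hD37	12	E+AA+HH+IP	E+AA+HH+IP	100	100
hD39	12	B+C+EE+FF+HH+OO+UU+DX	B+C+EE+FF+HH+OO+UU+DX	100	100
hD40	12	A+D+EE	A+D+EE	100	100
hD41	12	B+C+AA+NN+OO	B+C+AA+NN+OO	100	100
hD42	12	A+B+AA+DD+PP+UU	A+B+AA+DD+PP+UU	100	100
hD43	12	A+B+C+AA+EE+UU	A+B+C+AA+EE+UU	100	100
hD44	12	B+C+EE+FF+OO+PP+UU	B+C+EE+FF+OO+PP+UU	100	100
hD45	12	B+C+D+DD	B+C+D+DD	100	100
hD46	12	B+C+AA+DD	B+C+AA+DD	100	100
hD47	12	B+C+DD+FF	B+C+DD+FF	100	100
hD48	12	B+C+NN+OO	B+C+NN+OO	100	100
hNRs	12	NRs	NRs	100	100
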
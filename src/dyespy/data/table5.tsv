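esid	n_spectra	true_mixture	pred_mixture	proportion_pct	subset_recall_pct
hD10	15	(LL)+AX+DX+FX+GX	AX+DX+FX+GX	100	100
hD11	15	(LL)+CX+KX+JX	JX	100	100
hD12	15	(LL)+AX+BX+GX	AX+GX	100	100
hD13; hD49; hD52	45	HX	HX	100	100
hD14	15	AX+DX+FX+GX	AX+DX+FX+GX	100	100
hD50	15	IX	IX	100	100
hD52	15	DX	FX	100	0
hD53; hD57	30	NX	NX	100	100
hD54	15	FX+MX+OX	FX	100	100
hD55	15	JX+LX+MX+PX	JX+LX+MX+PX	100	100
hD56	15	AX+HX	AX+HX	100	100
hD58	15	KX		100	0
hD59	15	AX+BX+DX	AX+BX+DX	100	100
hD60	15	IX+NX	IX+NX	100	100
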
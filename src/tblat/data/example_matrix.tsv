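# prune_threshold=0.01
# provenance=worked example: state transitions for the 3-mers of 'abnormal'
abn	abn	0.490000
abn	bno	0.200000
abn	abo	0.030000
abn	bnr	0.020000
abn	bon	0.020000
abn	abd	0.010000
abn	bor	0.010000
bno	bno	0.320000
bno	abn	0.180000
bno	nor	0.130000
bno	abo	0.020000
bno	bnr	0.010000
bno	bon	0.010000
bno	nro	0.010000
bno	abd	0.010000
bno	dno	0.010000
nor	nor	0.410000
nor	orm	0.060000
nor	orr	0.040000
nor	eno	0.040000
nor	bno	0.020000
nor	ino	0.020000
nor	ono	0.020000
nor	ort	0.010000
nor	sno	0.010000
orm	orm	0.340000
orm	for	0.090000
orm	nor	0.080000
orm	rma	0.060000
orm	rmo	0.010000
orm	hor	0.010000
orm	rmi	0.010000
orm	rom	0.010000
rma	rma	0.340000
rma	orm	0.080000
rma	erm	0.060000
rma	mal	0.040000
rma	mat	0.040000
rma	arm	0.020000
rma	man	0.020000
rma	nor	0.010000
rma	mac	0.010000
mal	mal	0.400000
mal	rma	0.070000
mal	all	0.030000
mal	ali	0.020000
mal	ala	0.020000
mal	sma	0.020000
mal	ima	0.020000
mal	orm	0.020000
mal	oma	0.010000
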
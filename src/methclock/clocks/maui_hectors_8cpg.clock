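#methclock-model	v1
meta	alpha	0.9
meta	cpg_filter_threshold	10
meta	n_training	31
meta	training_set_label	maui_hectors_strict
intercept	-4.6720053
coef	cg00817637	0.2573007
coef	cg09026530	-2.0929561
coef	cg09402653	2.4794632
coef	cg09461098	-0.8055783
coef	cg16496042	2.7959477
coef	cg20582188	-9.9140532
coef	cg24276148	16.2120942
coef	cg25254739	-5.6220444
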
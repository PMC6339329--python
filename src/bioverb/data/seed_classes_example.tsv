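class_index	class_name	verb	origin
2.2.1	Biochemical modification	dephosphorylate	seed
2.2.1	Biochemical modification	phosphorylate	seed
4.1.3	Label	stain	seed
4.1.3	Label	label	seed
4.1.3	Label	immunoblot	seed
4.1.3	Label	probe	seed
4.1.3	Label	fix	seed
4.2.0	Precipitate	coprecipitate	seed
4.2.0	Precipitate	coimmunoprecipitate	seed
4.2.0	Precipitate	precipitate	seed
9.1.1	Examine	assess	seed
9.1.1	Examine	evaluate	seed
9.1.1	Examine	estimate	seed
9.1.1	Examine	examine	seed
9.1.1	Examine	explore	seed
9.1.1	Examine	analyze	seed
9.1.2	Establish	establish	seed
9.1.2	Establish	test	seed
9.1.2	Establish	investigate	seed
9.2.1	Presentational	argue	seed
9.2.1	Presentational	hypothesize	seed
9.2.1	Presentational	conclude	seed
9.2.1	Presentational	reason	seed
9.2.1	Presentational	note	seed
9.2.1	Presentational	speculate	seed
9.2.1	Presentational	assume	seed
10.1.1	Quantitate	quantify	seed
10.1.1	Quantitate	quantitate	seed
10.1.1	Quantitate	measure	seed
10.1.1	Quantitate	monitor	seed
11.0.0	Release	release	seed
11.0.0	Release	detach	seed
11.0.0	Release	excise	seed
11.0.0	Release	dissociate	seed
12.0.0	Use	utilize	seed
12.0.0	Use	employ	seed
12.0.0	Use	exploit	seed
14.0.0	Call	name	seed
14.0.0	Call	designate	seed
16.0.0	Appear	become	seed
16.0.0	Appear	occur	seed
16.0.0	Appear	seem	seed
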
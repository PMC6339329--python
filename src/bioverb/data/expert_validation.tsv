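class_index	class_name	domain	n_candidates	n_correct
7.1.0	Collect	general	9	6
9.1.1	Examine	general	21	19
9.3.0	Indicate	general	11	10
10.1.3	Conduct	general	2	2
13.1.0	Encompass	general	8	6
14.0.0	Call	general	5	4
16.0.0	Appear	general	19	16
1.1.2	Suppress	biomedical	2	2
1.1.4	Inactivate	biomedical	15	11
1.4.0	Modify	biomedical	8	6
2.3.0	Interact	biomedical	21	19
4.1.3	Label	biomedical	15	11
8.3.1	Transport	biomedical	19	17
11.0.0	Release	biomedical	11	10
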
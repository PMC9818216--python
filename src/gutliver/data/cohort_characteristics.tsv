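parameter	pair	mean_a	sd_a	n_a	mean_b	sd_b	n_b	printed_p
Age (Year)	Ctrl-LC	56.7	9.8	17	65.2	11.4	18	0.024
Age (Year)	Ctrl-HCC	56.7	9.8	17	70.2	5.0	10	<0.001
Age (Year)	LC-HCC	65.2	11.4	18	70.2	5.0	10	0.202
BMI	Ctrl-LC	23.1	1.51	17	26.2	3.6	18	0.002
BMI	Ctrl-HCC	23.1	1.51	17	25.0	4.1	10	0.094
BMI	LC-HCC	26.2	3.6	18	25.0	4.1	10	0.480
AST (U/L)	Ctrl-LC	30.9	3.5	17	35.6	10.8	18	0.097
AST (U/L)	Ctrl-HCC	30.9	3.5	17	43.3	17.1	10	0.007
AST (U/L)	LC-HCC	35.6	10.8	18	43.3	17.1	10	0.155
ALT (U/L)	Ctrl-LC	28.5	4.7	17	30.0	17.9	18	0.740
ALT (U/L)	Ctrl-HCC	28.5	4.7	17	48.1	30.0	10	0.013
ALT (U/L)	LC-HCC	30.0	17.9	18	48.1	30.0	10	0.055
Bilirubin (mg/dL)	LC-HCC	1.1	0.5	18	1.2	0.7	10	0.664
Albumin (g/dL)	LC-HCC	4.4	0.4	18	3.6	0.5	10	<0.001
T-Cholesterol (mg/dL)	LC-HCC	166.6	26.1	18	150.0	40.3	10	0.196
Triglyceride (mg/dL)	LC-HCC	108.6	54.8	18	99.4	59.1	10	0.682
HbA1c (%)	LC-HCC	6.1	1.2	18	6.1	0.9	10	0.999
Platelet (1000/uL)	LC-HCC	120.2	45.8	18	100.7	43.6	10	0.283
Child-Pugh score	LC-HCC	5.1	0.2	18	6.0	1.6	10	0.158
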
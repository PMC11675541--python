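branch	period_span_ma	count	period_myr
branch8	114-156	14	42
branch7	111-114	2	3
branch6	67-111	13	44
branch5	60-111	34	51
branch4	16.9-60	73	43.1
branch3	0.0051-67	81	66.99
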
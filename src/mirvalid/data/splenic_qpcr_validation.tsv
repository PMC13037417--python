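mirna_id	fold_regulation	p_value
miR-34a	2.24	0.007977
miR-135b	2.95	0.048684
miR-493	3.13	0.031991
miR-411	4.31	0.006456
miR-494	5.76	0.045127
miR-10a	-2.65	0.000077
miR-142	-3.70	0.000000
miR-146a	-4.54	0.000001
miR-328	-3.79	0.000003
miR-505	-2.81	0.000000
miR-150	-4.00	0.000133
miR-362	-2.27	0.000042
miR-203a	-4.03	0.000007
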
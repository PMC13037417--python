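mirna_id	fold_regulation	p_value
miR-10a	7.73	0.024233
miR-18a	2.74	0.002813
miR-142	5.32	0.018751
miR-503	3.21	0.005969
miR-146a	2.78	0.024394
miR-221	2.62	0.000225
miR-212	5.56	0.013431
miR-18b	2.69	0.000226
miR-32	3.64	0.000616
miR-188	4.57	0.001131
miR-362	4.11	0.001758
miR-223	11.31	0.010768
miR-328	-2.95	0.000337
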
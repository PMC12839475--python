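patient	age_years	sex	weight_kg	duration_years	tremor_frequency_hz	medication
1	79	M	77	7	14.31	none
2	82	M	98	11	14.89	gabapentin 1200 mg 3x daily
3	72	F	55	4	15.31	gabapentin 200 mg 2x daily
4	51	F	66	2	16.00	none
5	74	M	78	7	15.41	clonazepam 0.5 mg 2x daily
6	66	F	72	11	14.40	gabapentin 200 mg 1x daily
7	68	M	80	16	14.24	propranolol 10 mg 3x daily
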
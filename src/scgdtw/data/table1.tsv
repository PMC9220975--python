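subject_id	sex	age	lvef_pct	disease	cycles	pep_lvet_avg	pep_lvet_sd	tei_avg	tei_sd
Subject-01	F	22	29.0	HFrEF	72	0.45	0.03	0.52	0.05
Subject-02	F	22	70.9	Normal	85	0.24	0.01	0.29	0.04
Subject-03	F	23	77.1	Normal	56	0.22	0.01	0.32	0.05
Subject-04	F	24	63.6	Normal	95	0.22	0.01	0.28	0.03
Subject-05	F	26	71.5	Normal	79	0.18	0.01	0.33	0.04
Subject-06	F	26	74.0	Normal	78	0.20	0.01	0.27	0.03
Subject-07	F	27	67.5	Normal	83	0.22	0.01	0.33	0.04
Subject-08	F	34	34.0	HFrEF	52	0.37	0.04	0.61	0.07
Subject-09	F	37	61.4	Normal	81	0.27	0.02	0.41	0.06
Subject-10	F	43	61.3	Normal	34	0.25	0.01	0.40	0.04
Subject-11	F	43	65.0	Normal	98	0.27	0.02	0.36	0.02
Subject-12	F	47	73.3	Normal	64	0.22	0.01	0.27	0.04
Subject-13	F	60	34.0	HFrEF	75	0.35	0.02	0.55	0.08
Subject-14	F	60	42.0	HFmrEF	65	0.28	0.02	0.53	0.04
Subject-15	F	68	28.0	HFrEF	67	0.38	0.05	0.54	0.12
Subject-16	F	68	65.0	MI	80	0.30	0.02	0.32	0.05
Subject-17	F	70	39.0	MI	60	0.38	0.02	0.64	0.05
Subject-18	F	70	36.0	HFrEF	38	0.33	0.03	0.48	0.04
Subject-19	F	72	28.0	HFrEF	84	0.54	0.03	0.64	0.05
Subject-20	F	80	33.0	HFrEF	39	0.37	0.02	0.58	0.06
Subject-21	F	82	45.0	MI	62	0.32	0.02	0.60	0.10
Subject-22	F	84	57.0	MI	61	0.19	0.01	0.43	0.03
Subject-23	F	85	42.0	HFmrEF	88	0.38	0.02	0.49	0.05
Subject-24	F	85	27.0	HFrEF	89	0.38	0.03	0.61	0.06
Subject-25	F	90	35.0	HFrEF	60	0.40	0.02	0.54	0.05
Subject-26	F	91	39.8	HFrEF	89	0.40	0.03	0.55	0.05
Subject-27	M	21	70.4	Normal	62	0.19	0.01	0.30	0.04
Subject-28	M	23	65.9	Normal	61	0.23	0.01	0.35	0.04
Subject-29	M	23	69.5	Normal	90	0.24	0.01	0.32	0.03
Subject-30	M	24	66.2	Normal	76	0.24	0.02	0.38	0.06
Subject-31	M	24	69.9	Normal	70	0.23	0.01	0.30	0.02
Subject-32	M	24	64.4	Normal	82	0.25	0.02	0.34	0.04
Subject-33	M	25	62.0	Normal	69	0.26	0.02	0.34	0.06
Subject-34	M	27	48.0	HFmrEF	37	0.38	0.03	0.51	0.07
Subject-35	M	28	63.1	Normal	62	0.23	0.01	0.30	0.03
Subject-36	M	38	74.7	MI	76	0.17	0.01	0.28	0.04
Subject-37	M	44	58.0	MI	74	0.31	0.02	0.41	0.04
Subject-38	M	45	39.0	HFrEF	69	0.38	0.01	0.53	0.03
Subject-39	M	46	67.2	Normal	73	0.19	0.01	0.31	0.02
Subject-40	M	48	67.3	MI	75	0.21	0.01	0.44	0.05
Subject-41	M	49	50.3	HFpEF	70	0.33	0.02	0.51	0.05
Subject-42	M	51	67.2	Normal	78	0.24	0.01	0.29	0.03
Subject-43	M	48	55.8	MI	66	0.23	0.02	0.41	0.06
Subject-44	M	58	34.0	HFrEF	79	0.29	0.02	0.66	0.09
Subject-45	M	62	21.0	HFrEF	66	0.50	0.04	0.72	0.13
Subject-46	M	62	33.0	HFrEF	38	0.45	0.07	0.63	0.07
Subject-47	M	63	34.0	HFrEF	80	0.36	0.02	0.59	0.08
Subject-48	M	63	31.0	HFrEF	46	0.47	0.03	0.67	0.08
Subject-49	M	65	57.6	MI	73	0.24	0.02	0.43	0.03
Subject-50	M	66	52.0	MI	50	0.24	0.01	0.48	0.03
Subject-51	M	68	39.0	HFrEF	54	0.32	0.04	0.43	0.07
Subject-52	M	69	30.0	HFrEF	75	0.44	0.03	0.61	0.05
Subject-53	M	70	40.0	HFrEF	40	0.33	0.03	0.54	0.06
Subject-54	M	79	30.0	HFrEF	67	0.35	0.02	0.66	0.06
Subject-55	M	79	48.0	MI	78	0.29	0.01	0.54	0.04
Subject-56	M	88	39.0	HFrEF	106	0.29	0.01	0.47	0.06
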
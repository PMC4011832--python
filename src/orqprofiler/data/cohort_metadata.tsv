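sample_id	age	sex	rin	smoking	cause_of_death	delay_hours	origin
P01	46	F	7.7	never	Digestive hemorrhage	25	Africa
P02	50	F	6.8	unknown	Cerebral hemorrhage	49	European
P03	59	F	7.8	current	Septic shock	27	European
P04	61	F	8.1	current	Cerebral hemorrhage	16	European
P05	61	F	7.4	unknown	Cerebral hemorrhage	51	European
P06	68	F	5.9	never	Septic shock	26	European
P07	70	F	7.4	unknown	Cerebral hemorrhage	48	European
P08	72	F	8.5	never	Aortic dissection	9	European
P09	75	F	6.8	past	Cardiogenic shock	11	European
P10	75	F	7.5	never	Digestive hemorrhage	23	European
P11	79	F	6.3	never	Septic shock	21	European
P12	79	F	7.5	never	Cardiac infarction	24	European
P13	81	F	6.7	never	Cardiac infarction	23	European
P14	39	M	7.2	never	Cardiopulmonary stop on hypoxemia	17	European
P15	50	M	6.5	never	Cerebral hemorrhage	24	European
P16	52	M	8.4	current	Septic shock	27	European
P17	53	M	7.9	current	Cerebral hemorrhage	16	European
P18	54	M	6.6	past	Cryptococcal meningitis	22	European
P19	65	M	7.7	never	Respiratory failure	43	European
P20	67	M	6.5	current	Septic shock	24	European
P21	69	M	7	current	Respiratory failure	48	European
P22	70	M	7.3	never	Digestive hemorrhage	25	European
P23	74	M	6.8	unknown	Aortic dissection	46	European
P24	74	M	9	current	Septic shock lung	14	European
P25	75	M	6.4	never	Septic Shock	19	European
P26	79	M	6.8	current	Cardiac infarction	30	European
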
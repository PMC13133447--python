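id	age_years	sex	duration_deafness_years	years_ci_use	implant_side	azbio	electrodes_blocked
CI01	77	M	31	12	Bilateral	93	4
CI02	79	M	15	14	L	87	3
CI03	77	M	24	8	Bilateral	79	4
CI04	73	M	49	6	Bilateral	94	4
CI05	78	M	10	7	L	93	3
CI06	57	F	6	14	L	94	3
CI07	72	F	40	12	L	93	4
CI08	65	M	20	7	Bilateral	86	4
CI09	63	F	11	8	R	53	4
CI10	66	F	7	22	Bilateral	93	3
CI11	73	M	48	5	R	97	2
CI12	67	F	24	3	R	94	4
CI13	65	F	14	6	L	97	4
CI14	59	F	39	4	R	93	2
CI15	74	F	21	2	L	90	3
CI16	64	F	2	4	L	100	4
CI17	80	M	28	2	R	64	4
CI18	68	M	51	15	R	85	3
CI19	79	F	23	16	R	82	4
CI20	62	F	25	3	R	90	3
CI21	79	F	15	2	L	96	3
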
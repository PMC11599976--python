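case_id	breed	age_years	body_weight_kg	lameness	luxation	additional_diseases
1	Labrador R.	5	28.2	R 3/5	R MPL 3/4	R hip OA;R CCLR
2	Mixed-breed	0.8	37.4	L 3/5	L MPL 3/4	L hip OA
3	Boule dog	7	8.4	R 2/5	R MPL 2/4;L MPL 1/4	R hip OA
4	Appenzeller	6.2	19	R 2/5	R MPL 2/4	R Stifle OA
5	Mixed-breed	2.5	8.6	R 2/5	R MPL 2/4;L MPL 1/4
6	Newfoundland	0.9	41	L 3/5	L LPL 3/4	L hip OA
7	Mixed-breed	2.4	6.2	L 3/5	L MPL 3/4
8	Mixed-breed	1.4	31	R 3/5	R LPL 3/4	R hip OA
9	Mixed-breed	3.3	5.5	R 2/5	R MPL 2/4
10	Mixed-breed	3.1	6	R 2/5;L 1/5	R MPL 2/4;L MPL 1/4
11	Mixed-breed	3.1	4.5	R 1/5;L 1/5	R MPL 2/4;L MPL 1/4	R Stifle OA
12	Mixed-breed	8.5	7.8	L 2/5	L MPL 2/4
13	Yorkshire T.	4.3	4.5	R 2/5;L 1/5	R MPL 3/4;L MPL 2/4	R hip OA;R CCLR
14	Appenzeller	10.3	21	R 2/5	R MPL 3/4	R hip OA;R Stifle OA
15	Yorkshire T.	1.1	5.5	R 3/5;L 3/5	R MPL 4/4;L MPL 4/4
16	Mixed-breed	1.9	7.2	R 3/5;L 1/5	R LPL 4/4;L LPL 2/4
17	Yorkshire T.	8.7	6.4	R 2/5;L 1/5	R MPL 3/4
18	Yorkshire T.	11.3	5.3	R 2/5	R MPL 2/4;L MPL 1/4
19	Mixed-breed	3.1	17	R 3/5	L MPL 4/4	R hip OA
20	Mixed-breed	0.9	4.3	R 3/5;L 3/5	R LPL 4/4;L LPL 4/4	R hip OA;L hip OA
21	San Bernard	0.9	47.6	R 2/5	R MPL 2/4	R hip OA
22	Mixed-breed	0.11	3.7	R 3/5;L 3/5	R LPL 4/4;L LPL 4/4
23	Weimaraner	0.8	17.4	L 3/5	L MPL 3/4	L Stifle OA
24	Maltese	9	4.5	R 2/5	R MPL 4/4
25	Chihuahua	3.2	2.4	L 3/5	L MPL 3/4
26	Shiba-Inu	4.7	9	R 2/5	R MPL 3/4
27	Maltese	6.4	3.2	R 2/5	R MPL 3/4	R CCLR
28	Boule dog	4.2	9.8	R 2/5	R MPL 2/4
29	American Staffordshire	3.3	24.7	R 2/5	R MPL 2/4	R CCLR;R Stifle OA
30	Chihuahua	1.5	2	R 1/5;L 1/5	R MPL 2/4;L MPL 2/4
31	Labrador R.	2.5	28	R 2/5	R MPL 2/4	R hip OA;R CCLR
32	Segugio Italiano	7.2	16.8	R 4/5	R MPL 4/4	R hip OA;R Stifle OA
33	Setter inglese	3.3	17.8	L 2/5	L LPL 3/4
34	Bolognese	1.9	5.5	R 3/5;L 3/5	R MPL 4/4;L MPL 2/4
35	Yorkshire	1.7	2.1	R 4/5	R MPL 4/4
36	Segugio Italiano	4.6	17.2	R 2/5	R MPL 3/4	R hip OA
37	Labrador R.	7.8	26.4	R 1/5	R MPL 2/4
38	Chihuahua	2.1	2.7	R 1/5;L 1/5	R MPL 2/4;L MPL 2/4
39	Labrador R.	7.8	27	R 1/5	R MPL 4/4	R hip OA;R Stifle OA
40	Yorkshire	6.4	4.7	R 1/5;L 1/5	R MPL 2/4;L MPL 2/4
41	Mixed-breed	5.2	26.5	R 2/5	R MPL 2/4
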
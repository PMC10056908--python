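taxon	0	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	21	22	23	24	25	26	27	28	29	30	31	32	33	34	35	36	37	38
Xestocephalus asper	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	-	-	-	-	-	-	-	-	-	-	-	0	0
Aphrodes bicinctus	2	1	1	1	0	1	1	1	1	2	1	2	3	2	1	2	2	4	2	2	1	0	1	3	1	2	-	-	-	0	0	1	0	1	-	-	-	1	1
Aphrodes diminuta	2	1	1	1	0	1	1	1	1	2	1	2	3	2	1	2	2	4	2	2	1	0	1	3	1	2	-	-	-	0	0	1	0	0	-	-	-	1	1
Anoscopus albiger	0	1	1	0	0	0	0	0	1	2	1	2	3	1	1	3	3	3	2	2	1	0	1	2	0	2	2	0	2	1	2	-	-	-	-	-	-	1	3
Anoscopus serratulae	0	1	1	0	1	0	0	0	?	?	?	?	?	?	?	?	?	?	?	2	1	0	1	3	0	2	2	0	2	0	2	-	-	-	-	-	-	1	1
Stroggylocephalus agrestis	0	1	0	1	0	0	0	1	1	1	1	1	1	1	1	1	1	1	0	1	1	0	1	1	0	1	0	0	0	-	-	-	-	-	-	-	-	2	0
Stroggylocephalus livens	0	1	0	1	0	0	0	1	1	1	1	1	2	1	1	1	1	2	1	1	1	0	1	1	0	1	1	0	1	-	-	-	-	-	-	-	-	2	0
Planaphrodes angulaticeps	1	1	2	1	?	?	?	?	?	?	?	?	?	?	?	?	?	?	?	?	1	1	1	5	0	3	4	1	0	0	1	4	1	0	0	-	-	3	4
Planaphrodes araxicus	1	1	2	1	1	1	?	?	?	?	?	?	?	?	?	?	?	?	?	?	1	1	1	0	0	3	3	0	2	0	1	4	1	0	0	-	-	3	4
Planaphrodes baoxingensis	1	1	2	1	1	1	1	1	1	2	1	2	3	2	1	3	3	5	2	2	1	1	1	6	0	4	3	1	0	2	1	3	1	3	1	0	0	3	4
Planaphrodes bifasciatus	1	1	2	1	1	1	1	1	?	?	?	?	?	?	?	?	?	?	?	?	1	1	1	6	1	3	-	-	-	0	0	1	1	2	3	1	0	3	4
Planaphrodes elongatus	1	1	2	1	?	?	1	?	?	?	?	?	?	?	?	?	?	?	?	?	1	1	1	4	0	3	3	0	2	2	1	1	1	1	0	-	-	3	4
Planaphrodes faciems	1	1	2	1	1	1	1	1	1	2	1	2	3	2	1	3	3	5	2	2	1	1	1	6	0	5	3	1	0	2	1	3	1	3	2	0	0	3	4
Planaphrodes iranicus	1	1	2	1	?	?	1	?	?	?	?	?	?	?	?	?	?	?	?	?	1	1	1	4	0	3	4	1	0	2	1	1	1	3	0	-	-	3	3
Planaphrodes laevus	1	1	2	1	1	1	1	1	1	2	1	2	3	2	1	3	?	?	2	2	1	1	1	5	0	3	3	0	2	0	1	4	2	1	0	-	-	3	4
Planaphrodes lusitanicus	1	1	2	1	1	1	1	?	?	?	?	?	?	?	?	?	2	4	2	?	1	1	1	5	0	3	3	0	0	0	1	4	2	1	0	-	-	3	4
Planaphrodes modicus	1	1	2	1	1	1	1	1	?	?	?	?	3	?	?	?	2	4	2	?	1	1	1	0	0	3	3	0	2	0	1	2	1	0	0	-	-	3	4
Planaphrodes monticola	1	1	2	1	1	1	1	1	1	2	1	2	3	2	1	3	3	5	2	2	1	1	1	6	0	4	3	1	0	0	0	3	1	0	3	1	1	3	4
Planaphrodes nigricans	1	1	2	1	1	1	1	1	1	2	1	2	3	2	1	3	3	5	2	2	1	1	1	6	0	4	3	1	0	2	1	3	1	3	4	2	0	3	4
Planaphrodes nigritus	1	1	2	1	1	1	1	1	?	?	?	?	?	?	?	?	?	?	?	?	1	1	1	6	0	4	3	1	0	0	1	3	1	1	3	1	0	3	4
Planaphrodes nisamiana	1	1	2	1	1	?	1	?	?	?	?	?	?	?	?	?	2	4	2	?	1	1	1	4	0	3	3	1	0	3	0	1	1	3	0	-	-	3	3
Planaphrodes sahlbergii	1	1	2	1	1	1	1	1	1	2	1	2	3	2	1	3	2	4	2	2	1	1	1	0	0	3	3	1	0	0	1	4	1	2	0	-	0	3	4
Planaphrodes vallicola	1	1	2	1	1	1	1	?	?	?	?	?	3	?	?	?	2	4	2	?	1	1	1	6	0	2	-	-	-	0	0	0	-	-	4	2	-	3	2
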
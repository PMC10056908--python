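taxon	role	areas
Xestocephalus asper	root_outgroup	
Aphrodes bicinctus	outgroup	ABC
Aphrodes diminuta	outgroup	A
Anoscopus albiger	outgroup	A
Anoscopus serratulae	outgroup	A
Stroggylocephalus agrestis	outgroup	A
Stroggylocephalus livens	outgroup	A
Planaphrodes angulaticeps	ingroup	A
Planaphrodes araxicus	ingroup	B
Planaphrodes baoxingensis	ingroup	D
Planaphrodes bifasciatus	ingroup	ABC
Planaphrodes elongatus	ingroup	ABC
Planaphrodes faciems	ingroup	D
Planaphrodes iranicus	ingroup	B
Planaphrodes laevus	ingroup	AC
Planaphrodes lusitanicus	ingroup	A
Planaphrodes modicus	ingroup	A
Planaphrodes monticola	ingroup	AC
Planaphrodes nigricans	ingroup	D
Planaphrodes nigritus	ingroup	ABC
Planaphrodes nisamiana	ingroup	A
Planaphrodes sahlbergii	ingroup	CD
Planaphrodes vallicola	ingroup	AB
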
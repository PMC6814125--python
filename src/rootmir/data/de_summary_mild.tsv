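mirna_id	log2FC	pvalue	FDR
zma-miR399e,i,j-3p	3.39	1.1e-20	2.4e-18
zma-miR396c,d	-0.422	7.2e-09	3.2e-07
zma-miR319a-d-3p	-0.422	2.1e-08	7.6e-07
zma-miR168b-3p	-1.188	9.0e-07	2.4e-05
zma-miR408b-3p,a	-0.910	8.6e-07	2.4e-05
zma-miR167e-j-5p	0.653	9.7e-06	1.7e-04
zma-miR168a-3p	-0.985	4.9e-05	0.001
zma-miR169c-3p	-0.807	0.001	0.006
zma-miR169r-3p	-3.78	0.006	0.034
zma-miR159c,d-3p	0.294	0.008	0.044
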
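mirna_id	log2FC	pvalue	FDR
zma-miR396c,d	-0.877	6.7e-32	4.8e-30
zma-miR319a-d-3p	-0.855	1.1e-28	6.0e-27
zma-miR393b-3p	2.14	2.7e-23	9.6e-22
zma-miR167e-j-5p	1.26	1.1e-17	2.5e-16
zma-miR390a,b-5p	-1.23	3.4e-17	6.1e-16
zma-miR393a,c-5p	2.07	5.8e-17	9.5e-16
zma-miR393b-5p	2.04	1.9e-16	2.4e-15
zma-miR408b-3p,a	-1.56	1.7e-15	2.0e-14
zma-miR168b-3p	-1.34	8.6e-08	8.4e-07
zma-miR319b,d-5p	-0.832	2.1e-06	1.8e-05
zma-miR166a-3p	-0.296	2.5e-05	1.9e-04
zma-miR444a,b	1.17	3.6e-05	2.6e-04
zma-miR399e,i,j-3p	1.82	3.8e-05	2.7e-04
zma-miR8155	-0.791	2.1e-04	0.001
zma-miR166a-5p	-0.895	2.7e-04	0.002
zma-miR5139	-0.759	3.5e-04	0.002
zma-miR156a-i,l-5p	0.327	4.3e-04	0.002
zma-miR390a,b-3p	-1.27	0.002	0.008
zma-miR166c-5p,e	-0.721	0.002	0.009
zma-miR169c-3p	-0.750	0.002	0.010
zma-miR396a,b-3p	-0.797	0.003	0.011
zma-miR827-3p	-0.549	0.003	0.012
zma-miR169f-5p,g,h	-1.13	0.004	0.015
zma-miR167c-3p	-3.99	0.005	0.018
zma-miR156h-3p	-0.800	0.006	0.021
zma-miR399a,c,h-3p	-1.240	0.007	0.026
zma-miR156i-3p	-3.77	0.008	0.028
zma-miR156a-3p	1.45	0.009	0.030
zma-miR167e-3p	0.837	0.010	0.032
zma-miR167a-d-5p	0.670	0.014	0.045
zma-miR398b-5p	-0.670	0.015	0.048
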
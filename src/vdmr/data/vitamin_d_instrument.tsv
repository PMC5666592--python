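rsid	chr	locus	effect_allele	beta	pvalue
rs2282679	4	GC	G	-4.67	<3.4e-302
rs10741657	11	CYP2R1	G	-1.72	6.5e-81
rs12785878	11	DHCR7/NADSYN1	G	-2.11	6.4e-129
rs6013897	20	CYP24A1	A	-0.98	3.4e-17
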
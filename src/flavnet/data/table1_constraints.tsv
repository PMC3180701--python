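# Preliminary flux constraints for the reference state (rates in
# mmol/kg/h).  Fixed-value rows pin a product-formation rate derived from a
# tissue concentration (mg/kg divided by molar mass, g/mol); range rows
# bound rates measured in other species; the "mue" row is the lignin-growth
# coupling (biomass_fraction * growth rate = 0.15 * 0.18).  The flavan-3-ol
# rows share a class-total concentration of 40.4 mg/kg converted with the
# mean molar mass of the four compounds and split equally.  Note the
# kaempferol-3-glucoside rate is carried exactly as printed even though it
# does not match that compound's molar mass (~448.4 g/mol); see the methods
# note.
label	compound_id	reaction_id	mg_per_kg	molar_mass	min	max	provenance
lignin growth contribution		mue			2.70E-02	2.70E-02	fixed-value
cyanidin 3-glucoside	CPD1F-766	RXN1F-775	28.9	449.4	6.43E-02	6.43E-02	fixed-value
cyanidin 3-p-coumaroylglucoside	CPD-7866	RXN-8204	1.4	595.5	2.35E-03	2.35E-03	fixed-value
kaempferol-3-glucoside	CPD1F-453	RXN1F-461	97.7		1.64E-01	1.64E-01	fixed-value
quercetin-3-glucoside	CPD1F-437	RXN1F-462	37.3	464.4	8.03E-02	8.03E-02	fixed-value
epiafzelechin	CPD-10413	RXN-9724		274.27	3.58E-02	3.58E-02	fixed-value
2,3-cis-epicatechin	CPD-7630	RXN-9725		290.27	3.58E-02	3.58E-02	fixed-value
afzelechin	CPD-1962	RXN-1481		274.27	3.58E-02	3.58E-02	fixed-value
2,3-trans-catechin	CPD-1961	RXN-1484		290.27	3.58E-02	3.58E-02	fixed-value
luteolin	5734-TETRAHYDROXYFLAVONE				0	5.02E+01	range
apigenin	CPD-431				0	1.44E+01	range
methylsalicylate	METHYLSALICYLATE				0	1.15E-02	range
methylbenzoate	METHYLBENZOATE				0	2.27E+01	range
4-coumarate	4-COUMARATE				0	1.84E+00	range
caffeate	CAFFEATE				0	3.10E-01	range
ferulate	FERULATE				0	4.50E-01	range
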
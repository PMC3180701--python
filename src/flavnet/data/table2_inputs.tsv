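# Boundary input fluxes of the reference state, held constant across all
# knockout simulations (rates in mmol/kg/h).
reaction_id	rate
CAFFEATE-O-METHYLTRANSFERASE-RXN	8.40E+01
CONIFERIN-BETA-GLUCOSIDASE-RXN	4.51E+01
BENZYL-ALC-DEHYDROGENASE-RXN	2.98E+01
RXN-5482	1.44E+00
CINNAMYL-ALCOHOL-DEHYDROGENASE-RXN	9.26E+01
TYROSINE-DECARBOXYLASE-RXN	1.01E+02
PHEAMINOTRANS-RXN	9.26E+01
MANDELONITRILE-LYASE-RXN	2.98E+01
UDP-GLUCOSE-4,6-DEHYDRATASE-RXN	2.41E+00
DAHPSYN-RXN	9.07E+01
TYROSINE-AMINOTRANSFERASE-RXN	6.17E+01
PHENYLPYRUVATE-DECARBOXYLASE-RXN	5.00E+01
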
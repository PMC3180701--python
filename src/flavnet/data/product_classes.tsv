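# Partial curation of external product compounds into product classes
# (flavonoid subclasses, non-flavonoid groups).  Reconstructed from the
# printed constraint and composition tables; compounds whose database ids
# are not printed anywhere are necessarily absent, so this map is a
# starting point to extend when the full subnetwork model is available.
class	compound_id	name
anthocyanins	CPD1F-766	cyanidin 3-glucoside
anthocyanins	CPD-7866	cyanidin 3-p-coumaroylglucoside
flavonols1	CPD1F-453	kaempferol-3-glucoside
flavonols2	CPD1F-437	quercetin-3-glucoside
proanthocyanidins	CPD-10413	epiafzelechin
proanthocyanidins	CPD-7630	2,3-cis-epicatechin
proanthocyanidins	CPD-1962	afzelechin
proanthocyanidins	CPD-1961	2,3-trans-catechin
flavones	5734-TETRAHYDROXYFLAVONE	luteolin
flavones	CPD-431	apigenin
flavanones	CPD-3041	liquiritigenin
lignin	CONIFERYL-ALCOHOL	coniferyl alcohol
lignin	SINAPYL-ALCOHOL	sinapyl alcohol
lignin	COUMARYL-ALCOHOL	coumaryl alcohol
benzenoids	METHYLSALICYLATE	methylsalicylate
benzenoids	METHYLBENZOATE	methylbenzoate
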
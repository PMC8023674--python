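# CURIE prefix registry: per-namespace accession syntax, implied PSI-MI
# interactor type, applicable entity classes and preference rank.
# Curators can extend this table (or ship a modified copy) without code
# changes.  entity_types is ";"-separated; empty fields are "-".
# rank: primary | alternative (term/reference namespaces carry "primary").
prefix	pattern	implied_type	entity_types	rank
uniprotkb	([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})(-\d+)?	mi:0326	protein	primary
ncbigene	\d+	-	gene;protein	alternative
ensembl	ENS[A-Z]{0,5}(G|T|P|E)\d{11}(\.\d+)?	-	gene;mrna	primary
rnacentral	URS[0-9A-F]{10}(_\d+)?	mi:0320	mrna	alternative
chebi	\d+	mi:0328	chemical	primary
pubchem.compound	\d+	mi:0328	chemical	alternative
complexportal	CPX-\d+	mi:0314	complex	primary
interpro	IPR\d{6}	mi:1304	family	primary
pfam	PF\d{5}	mi:1304	family	alternative
go	\d{7}	-	phenotype	primary
mi	\d{4}	-	-	primary
ro	\d{7}	-	-	primary
eco	\d{7}	-	-	primary
mod	\d{5}	-	-	primary
so	\d{7}	-	-	primary
obi	\d{7}	-	-	primary
bto	\d{7}	-	-	primary
cl	\d{7}	-	-	primary
uberon	\d{7}	-	-	primary
po	\d{7}	-	-	primary
fao	\d{7}	-	-	primary
cellosaurus	CVCL_[A-Z0-9]{4}	-	-	primary
ncbitaxon	\d+	-	-	primary
pubmed	\d+	-	-	primary
doi	10\.\S+	-	-	primary
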
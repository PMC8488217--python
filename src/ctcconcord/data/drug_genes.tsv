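gene	drug	association
EGFR	erlotinib	sensitivity/resistance by mutation site
EGFR	gefitinib	sensitivity/resistance by mutation site
EGFR	osimertinib	resistance (p.L718Q and others)
TP53	cisplatin	reduced response
TP53	carboplatin	reduced response
ABCC11	cisplatin	efflux-mediated resistance
ABCG2	platinum compounds	efflux-mediated resistance
MUC16	cisplatin	resistance via p53 downregulation
MUC16	gemcitabine	resistance via p53 downregulation
SHKBP1	erlotinib	resistance in stem-cell-like cells
CSMD3	etoposide	resistance
CYP2C9	cyclophosphamide	altered metabolism
CYP2C19	cyclophosphamide	altered metabolism
CYP26B1	retinoids	altered metabolism
SLCO1B1	methotrexate	altered transport
ST6GAL2	platinum compounds	candidate resistance
RRAD	platinum compounds	candidate response modifier
MDM2	multi-drug	p53 pathway resistance
NUP107	multi-drug	candidate resistance
UMPS	fluoropyrimidines	altered metabolism
NUMA1	multi-drug	cell-cycle-mediated resistance
ZNF143	multi-drug	cell-cycle-mediated resistance
ELP3	multi-drug	candidate resistance
RXRG	chemotherapy	candidate response modifier
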
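# Synthetic compound panel around 2,4-dihydroxyaniline: an aminophenol
# family (structurally similar to the query) plus dissimilar aliphatic
# and miscellaneous compounds.  Structures are real; the panel itself is
# a constructed stand-in for a proprietary reference dataset.
Nc1ccc(O)cc1O	dihydroxyaniline_24	2,4-dihydroxyaniline
Nc1ccc(O)cc1	aminophenol_4	4-aminophenol
Nc1cccc(O)c1	aminophenol_3	3-aminophenol
Nc1ccccc1O	aminophenol_2	2-aminophenol
Nc1cc(O)ccc1O	dihydroxyaniline_25	2,5-dihydroxyaniline
Nc1ccc(O)c(O)c1	dihydroxyaniline_34	3,4-dihydroxyaniline
Cc1ccc(O)cc1N	methyl_aminophenol	2-amino-4-methylphenol
Nc1ccc(OC)cc1O	methoxy_aminophenol	2-amino-5-methoxyphenol
Oc1ccc(O)cc1	hydroquinone	hydroquinone
Oc1ccccc1O	catechol	catechol
Oc1cccc(O)c1	resorcinol	resorcinol
Nc1ccccc1	aniline	aniline
Nc1ccc(N)cc1	phenylenediamine_14	1,4-phenylenediamine
Nc1ccccc1N	phenylenediamine_12	1,2-phenylenediamine
Oc1ccccc1	phenol	phenol
Cc1ccc(O)cc1	cresol_4	4-cresol
Nc1ccc(C)cc1	toluidine_4	4-toluidine
Oc1ccc(Cl)cc1	chlorophenol_4	4-chlorophenol
Nc1ccc(Cl)cc1	chloroaniline_4	4-chloroaniline
CCO	ethanol	ethanol
CCCCCCO	hexanol	1-hexanol
CC(C)=CCCC(C)(O)C=C	linalool	(+/-)-linalool
CCCCCCCC	octane	octane
CC(=O)CC	butanone	2-butanone
CCOC(C)=O	ethyl_acetate	ethyl acetate
CCCCCC=O	hexanal	hexanal
OCC(O)CO	glycerol	glycerol
CCCCCCCCO	octanol	1-octanol
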
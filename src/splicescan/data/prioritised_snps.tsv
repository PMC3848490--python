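proxy_snp	snp	p_value	trait	risk_allele	pubmed_id	r2	host_gene	ref	alt	consequence	category
rs11078928	rs2872507	5e-11	Ulcerative colitis	A	21297633	1	GSDMB	A	G	essential_splice_site	acceptor_destroyed
rs11078928	rs2872507	5e-9	Crohn's disease	A	18587394	1	GSDMB	A	G	essential_splice_site	acceptor_destroyed
rs11078928	rs9303277	2e-9	Primary biliary cirrhosis	T	20639880	0.905	GSDMB	A	G	essential_splice_site	acceptor_destroyed
rs11078928	rs2290400	6e-13	Type 1 diabetes	?	19430480	0.905	GSDMB	A	G	essential_splice_site	acceptor_destroyed
rs11078928	rs7216389	9e-11	Asthma	T	17611496	0.905	GSDMB	A	G	essential_splice_site	acceptor_destroyed
rs2014886	rs703842	5e-11	Multiple sclerosis	A	19525955	0.964	TSFM	C	T	essential_splice_site	cryptic_donor_created
rs1260326	rs780094	7e-15	C-reactive protein	A	18439548	0.933	GCKR	T	C	splice_region	site_score_changed
rs1260326	rs780093	5e-11	Crohn's disease	T	21102463	0.901	GCKR	T	C	splice_region	site_score_changed
rs10263341	rs886774	3e-8	Ulcerative colitis	G	19915572	0.803	DLD	T	C	splice_region	ppt_weakened
rs1322077	rs2301436	1e-12	Crohn's disease	T	18587394	0.904	FGFR1OP	T	C	splice_region	ppt_weakened
rs2020854	rs2066808	1e-9	Psoriasis	A	19169254	1	STAT2	A	G	splice_region	cryptic_donor_created
rs55719896	rs8049439	2e-9	Inflammatory bowel disease, early onset	G	19915574	0.965	ATXN2L	G	A	splice_region	cryptic_acceptor_destroyed
rs55719896	rs4788084	3e-13	Type 1 diabetes	G	19430480	0.824	ATXN2L	G	A	splice_region	cryptic_acceptor_destroyed
rs3764021	rs3764021	5e-8	Type 1 diabetes	G	17554300	1	CLEC2D	C	T	splice_region	cryptic_donor_created
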
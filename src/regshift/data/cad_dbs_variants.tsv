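rsid	chrom	pos	ref	alt	dbs	annotation
rs56170783	chr1	56550459	A	C	chr1-56549815-56550830	PLPP3 intron
rs17048367	chr1	218660548	A	G,T	chr1-218660506-218661540	Intergenic region
rs7068966	chr10	12235993	C	G,T	chr10-12234966-12236001	CDC123 intron
rs77376996	chr2	187424445	T	TCTC,TCTCA	chr2-187423908-187424925	CALCRL intron
rs62172376	chr2	187424447	C	A	chr2-187423908-187424925	CALCRL intron
rs1537372	chr9	22103184	G	A,T	chr9-22103132-22104146	CDKN2B intron
rs1537373	chr9	22103342	T	A,G	chr9-22103132-22104146	CDKN2B intron
rs1333042	chr9	22103814	A	C,G	chr9-22103132-22104146	CDKN2B intron
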
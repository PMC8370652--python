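# per-mutant table; coordinates are placeholders consistent with gene-level classes
isolate_id	experiment	gene_name	coord_system	position	ref	alt	structural_flag	notes
WS001	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS002	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS003	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS004	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS005	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS006	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS007	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS008	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS009	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS010	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS011	wt	wspF	cds_nt	812	T	G		S2-transcribed V271G
WS012	wt	wspF	cds_nt	664	A	C		reconstructed
WS013	wt	wspF	cds_nt	143	G	A		reconstructed
WS014	wt	wspF	cds_nt	300	G			reconstructed frameshift
WS015	wt	wspF	cds_nt	449	G	T		reconstructed
WS016	wt	wspE	cds_nt	1724	C	T		reconstructed
WS017	wt	awsX	cds_nt	148	CTGCAGCTC			repeat-mediated 9-bp del
WS018	wt	awsX	cds_nt	148	CTGCAGCTC			repeat-mediated 9-bp del
WS019	wt	awsX	cds_nt	148	CTGCAGCTC			repeat-mediated 9-bp del
WS020	wt	awsX	cds_nt	298	ATCGCC			repeat-mediated 6-bp del
WS021	wt	awsX	cds_nt	179	T	C		reconstructed
WS022	wt	awsX	cds_nt	179	T	C		reconstructed
WS023	wt	awsX	cds_nt	329	T	A		reconstructed
WS024	wt	awsX	cds_nt	43	G	C		reconstructed
WS025	wt	awsX	cds_nt	373	G	T		reconstructed
WS026	wt	awsR	cds_nt	80	C	T		reconstructed
WS027	wt	awsR	cds_nt	509	C	T		reconstructed
WS028	wt	awsR	cds_nt	454	G	A		reconstructed
WS029	wt	awsX	upstream_nt	-120			promoter_capture	rRNA-terminator disruption; reconstructed breakpoint
WS030	wt	awsX	upstream_nt	-85			promoter_capture	rRNA-terminator disruption; reconstructed breakpoint
WS031	wt	mwsR	cds_nt	2938	G	A		reconstructed
WS032	wt	mwsR	cds_nt	2938	G	A		reconstructed
WS033	wt	mwsR	cds_nt	3013	C	T		reconstructed
WS034	wt	mwsR	cds_nt	2968	CAAAGG			repeat-mediated 6-bp del
WS035	wt	mwsR	cds_nt	2608	G	A		reconstructed
WS036	wt	mwsR	cds_nt	3539	G	A		reconstructed
WS037	wt	mwsR	cds_nt	2429	G	A		reconstructed
WS038	wt	mwsR	cds_nt	2188	C	T		reconstructed
WS039	wt	mwsR	cds_nt	3149	C	T		reconstructed
WS040	wt	mwsR	cds_nt	3360	G	A		reconstructed
WS041	wt	PFL_3078	upstream_nt	-35	C	T		reconstructed upstream point
WS042	wt	PFL_3078	upstream_nt	-44	C	T		reconstructed upstream point
WS043	wt	PFL_3078	upstream_nt	-10	C	T		reconstructed upstream point
WS044	triple_deletion	PFL_0087	cds_nt	689	A	G		reconstructed
WS045	triple_deletion	PFL_0087	cds_nt	898	G	A		reconstructed
WS046	triple_deletion	PFL_0087	cds_nt	434	C	T		reconstructed
WS047	triple_deletion	PFL_0087	cds_nt	262	G	A		reconstructed
WS048	triple_deletion	PFL_0087	cds_nt	1228	T	C		reconstructed
WS049	triple_deletion	PFL_0087	cds_nt	163	C	T		reconstructed
WS050	triple_deletion	PFL_3078	upstream_nt	-22	G	A		reconstructed upstream point
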
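# predicted mutational regions; residue spans are best-effort transcriptions
gene_name	kind	start	end	allowed_classes	region_id
wspF	aa_range	2	330	nonsense,frameshift_indel,inframe_indel	wspF_lof
wspF	aa_range	200	250	missense	wspF_ms1
wspF	aa_range	260	300	missense	wspF_ms2
wspE	aa_range	560	600	missense	wspE_phos
wspA	aa_range	270	330	missense	wspA_tip
wspA	aa_range	350	380	inframe_indel	wspA_meth
wspR	aa_range	170	185	missense,inframe_indel	wspR_linker
awsX	aa_range	2	140	inframe_indel	awsX_if
awsX	aa_range	40	80	missense	awsX_ms
awsR	aa_range	5	40	missense	awsR_peri
awsR	aa_range	61	90	missense	awsR_tm
awsR	aa_range	160	185	missense	awsR_hamp
awsO	aa_range	40	55	missense	awsO_dim
mwsR	aa_range	720	730	missense	mwsR_pas1
mwsR	aa_range	800	810	missense	mwsR_pas2
mwsR	aa_range	860	871	missense	mwsR_pas3
mwsR	aa_range	975	985	missense	mwsR_inter_ms1
mwsR	aa_range	1000	1010	missense	mwsR_inter_ms2
mwsR	aa_range	950	1020	inframe_indel	mwsR_inter_if
mwsR	aa_range	1045	1056	missense	mwsR_dgc
mwsR	aa_range	1175	1186	missense	mwsR_pde
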
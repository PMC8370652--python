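# Null-model parameterization.
# The frameshift:substitution per-site rate ratio is the single
# calibrated free parameter, fitted once so pathway marginals
# reproduce 54/30/16 and then frozen here.
rates:
  missense: 1.0
  nonsense: 1.0
  frameshift_indel: 0.246114
  inframe_indel: 1.0
  promoter_point: 0.0
normalization_scope: three_pathways
homopolymer_multiplier: 1.0
min_repeat_len: 6
max_deletion_len: 500
constraints:
  wspF: any_lof
  wspE: regions_only
  wspA: regions_only
  wspR: regions_only
  awsX: inframe_only
  awsR: regions_only
  awsO: regions_only
  mwsR: regions_only
calibration:
  parameter: rates.frameshift_indel
  value: 0.246114
  objective: Wsp pathway marginal = 0.54 over the three pathways
  result:
    Aws: 0.300879
    Mws: 0.159121
    Wsp: 0.540000
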
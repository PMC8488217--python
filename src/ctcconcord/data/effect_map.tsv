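annotator_effect	effect_class
nonsynonymous SNV	nonsynonymous_snv
nonsynonymous_SNV	nonsynonymous_snv
missense_variant	nonsynonymous_snv
stopgain	stopgain
stop_gained	stopgain
stoploss	stoploss
stop_lost	stoploss
frameshift insertion	frameshift_indel
frameshift deletion	frameshift_indel
frameshift_variant	frameshift_indel
nonframeshift insertion	nonframeshift_indel
nonframeshift deletion	nonframeshift_indel
inframe_insertion	nonframeshift_indel
inframe_deletion	nonframeshift_indel
splicing	splicing
splice_acceptor_variant	splicing
splice_donor_variant	splicing
synonymous SNV	synonymous
synonymous_variant	synonymous
unknown	other
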
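sequence,activity_class,ec50,ec50_unit,source
KA,dpp4_inhibitor,6.27,mM,"dry-cured ham, in vitro IC50"
AAATP,dpp4_inhibitor,6.47,mM,"dry-cured ham, in vitro IC50"
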
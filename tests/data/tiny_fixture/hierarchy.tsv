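parent	child
all_disease	group0_level0
all_disease	group1_level0
group0_level0	disease_00
group0_level0	disease_01
group0_level0	disease_02
group1_level0	disease_03
group1_level0	disease_04
group1_level0	disease_05
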
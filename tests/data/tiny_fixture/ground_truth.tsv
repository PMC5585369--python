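kind	mirna	disease
planted_error	mir-006	disease_05
held_out	mir-008	disease_02
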
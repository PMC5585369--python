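mirna	family
mir-000	fam01
mir-001	fam00
mir-002	fam00
mir-003	fam01
mir-004	fam00
mir-005	fam01
mir-006	fam01
mir-007	fam01
mir-008	fam01
mir-009	fam00
mir-010	fam02
mir-011	fam03
mir-012	fam02
mir-013	fam03
mir-014	fam02
mir-015	fam03
mir-016	fam03
mir-017	fam03
mir-018	fam01
mir-019	fam02
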
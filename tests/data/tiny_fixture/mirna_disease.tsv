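mirna	disease
mir-000	disease_01
mir-001	disease_02
mir-002	disease_00
mir-002	disease_02
mir-003	disease_01
mir-004	disease_01
mir-004	disease_02
mir-005	disease_02
mir-006	disease_00
mir-006	disease_01
mir-006	disease_02
mir-006	disease_05
mir-007	disease_01
mir-008	disease_00
mir-008	disease_01
mir-008	disease_03
mir-009	disease_02
mir-010	disease_04
mir-010	disease_05
mir-011	disease_03
mir-011	disease_04
mir-011	disease_05
mir-012	disease_03
mir-012	disease_04
mir-012	disease_05
mir-013	disease_03
mir-013	disease_05
mir-014	disease_03
mir-014	disease_04
mir-014	disease_05
mir-015	disease_03
mir-015	disease_04
mir-015	disease_05
mir-016	disease_05
mir-017	disease_04
mir-017	disease_05
mir-018	disease_03
mir-018	disease_04
mir-018	disease_05
mir-019	disease_04
mir-019	disease_05
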
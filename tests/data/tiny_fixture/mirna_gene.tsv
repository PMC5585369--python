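mirna	gene
mir-000	gene000
mir-000	gene001
mir-000	gene002
mir-000	gene003
mir-000	gene004
mir-000	gene005
mir-001	gene000
mir-001	gene001
mir-001	gene002
mir-001	gene003
mir-001	gene005
mir-002	gene000
mir-002	gene001
mir-002	gene002
mir-002	gene003
mir-002	gene004
mir-002	gene005
mir-003	gene000
mir-003	gene001
mir-003	gene004
mir-004	gene000
mir-004	gene002
mir-004	gene003
mir-004	gene004
mir-005	gene002
mir-005	gene003
mir-005	gene005
mir-006	gene000
mir-006	gene002
mir-006	gene003
mir-006	gene004
mir-007	gene000
mir-007	gene001
mir-007	gene002
mir-007	gene003
mir-007	gene004
mir-007	gene005
mir-008	gene000
mir-008	gene001
mir-008	gene003
mir-008	gene004
mir-008	gene005
mir-009	gene000
mir-009	gene001
mir-009	gene002
mir-009	gene003
mir-009	gene005
mir-009	gene010
mir-010	gene006
mir-010	gene007
mir-010	gene008
mir-010	gene009
mir-010	gene010
mir-011	gene006
mir-011	gene007
mir-011	gene008
mir-011	gene010
mir-011	gene011
mir-012	gene006
mir-012	gene007
mir-012	gene008
mir-012	gene009
mir-012	gene010
mir-012	gene011
mir-013	gene006
mir-013	gene007
mir-013	gene008
mir-013	gene009
mir-013	gene010
mir-013	gene011
mir-014	gene011
mir-015	gene006
mir-015	gene007
mir-015	gene008
mir-015	gene009
mir-015	gene010
mir-015	gene011
mir-016	gene006
mir-016	gene009
mir-016	gene010
mir-016	gene011
mir-017	gene007
mir-017	gene008
mir-017	gene010
mir-017	gene011
mir-018	gene007
mir-018	gene011
mir-019	gene006
mir-019	gene007
mir-019	gene010
mir-019	gene011
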
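mirna	chrom	start	end	strand
mir-000	chr1	1043897	1043982	+
mir-001	chr1	1006096	1006175	-
mir-002	chr1	1001618	1001705	-
mir-003	chr1	1000615	1000678	+
mir-004	chr1	1036129	1036222	+
mir-005	chr1	1014768	1014866	+
mir-006	chr1	1015769	1015846	+
mir-007	chr1	1015096	1015176	-
mir-008	chr1	1036912	1037003	-
mir-009	chr1	1005529	1005604	-
mir-010	chr2	2002208	2002303	-
mir-011	chr2	2014195	2014286	-
mir-012	chr2	2002160	2002224	-
mir-013	chr2	2049956	2050016	-
mir-014	chr2	2006826	2006912	-
mir-015	chr2	2004522	2004609	-
mir-016	chr2	2043173	2043234	+
mir-017	chr2	2012041	2012119	+
mir-018	chr2	2042718	2042809	-
mir-019	chr2	2009910	2009970	-
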
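SYN_PW01	synthetic amino acid metabolism	met_000	met_001	met_002	met_003	met_004	met_005	met_006	met_007	met_008	met_009
SYN_PW02	synthetic carnitine shuttle	met_005	met_006	met_007	met_008	met_009	met_010	met_011	met_012	met_013	met_014
SYN_PW03	synthetic TCA cycle derivatives	met_010	met_011	met_012	met_013	met_014	met_015	met_016	met_017	met_018	met_019	met_020	met_021	met_022	met_023	met_024
SYN_PW04	synthetic lipid signalling	met_020	met_021	met_022	met_023	met_024	met_025	met_026	met_027	met_028	met_029	met_030	met_031	met_032	met_033	met_034	met_035	met_036	met_037	met_038	met_039
SYN_PW05	synthetic nucleotide turnover	met_030	met_031	met_032	met_033	met_034	met_035	met_036	met_037	met_038	met_039	met_040	met_041	met_042	met_043	met_044	met_045	met_046	met_047	met_048	met_049
SYN_PW06	synthetic carbohydrate pool	met_045	met_046	met_047	met_048	met_049	met_050	met_051	met_052	met_053	met_054	met_055	met_056	met_057	met_058	met_059	met_060	met_061	met_062
SYN_PW07	synthetic membrane transport	met_000	met_002	met_015	met_030	met_045
SYN_PW08	synthetic urea handling	met_050	met_051	met_052	met_053	met_054	met_055	met_056	met_057	met_058	met_059	met_060	met_061	met_062
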
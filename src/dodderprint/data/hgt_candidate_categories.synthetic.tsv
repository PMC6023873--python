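gene_id	category
hgt_cand_001	albumin
hgt_cand_002	albumin
hgt_cand_003	albumin
hgt_cand_004	albumin
hgt_cand_005	albumin
hgt_cand_006	albumin
hgt_cand_007	albumin
hgt_cand_008	strictosidine_synthase_like
hgt_cand_009	strictosidine_synthase_like
hgt_cand_010	novel
hgt_cand_011	novel
hgt_cand_012	novel
hgt_cand_013	novel
hgt_cand_014	novel
hgt_cand_015	novel
hgt_cand_016	novel
hgt_cand_017	novel
hgt_cand_018	novel
hgt_cand_019	novel
hgt_cand_020	novel
hgt_cand_021	novel
hgt_cand_022	novel
hgt_cand_023	novel
hgt_cand_024	novel
hgt_cand_025	novel
hgt_cand_026	novel
hgt_cand_027	novel
hgt_cand_028	novel
hgt_cand_029	novel
hgt_cand_030	novel
hgt_cand_031	novel
hgt_cand_032	novel
hgt_cand_033	novel
hgt_cand_034	novel
hgt_cand_035	novel
hgt_cand_036	novel
hgt_cand_037	novel
hgt_cand_038	novel
hgt_cand_039	novel
hgt_cand_040	novel
hgt_cand_041	novel
hgt_cand_042	novel
hgt_cand_043	novel
hgt_cand_044	novel
hgt_cand_045	novel
hgt_cand_046	novel
hgt_cand_047	novel
hgt_cand_048	novel
hgt_cand_049	novel
hgt_cand_050	novel
hgt_cand_051	novel
hgt_cand_052	novel
hgt_cand_053	novel
hgt_cand_054	novel
hgt_cand_055	novel
hgt_cand_056	novel
hgt_cand_057	novel
hgt_cand_058	novel
hgt_cand_059	novel
hgt_cand_060	novel
hgt_cand_061	novel
hgt_cand_062	novel
hgt_cand_063	novel
hgt_cand_064	novel
hgt_cand_065	novel
hgt_cand_066	novel
hgt_cand_067	novel
hgt_cand_068	novel
hgt_cand_069	novel
hgt_cand_070	novel
hgt_cand_071	novel
hgt_cand_072	novel
hgt_cand_073	novel
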
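# synthetic clinic roster fixture: 180 clinics with the four exclusion groups (5 level-1, 5 with no enrolments, 24 co-located with a referral clinic, 13 in another study)
clinic_id,governorate,annual_enrolments,is_level1,no_enrolments_prev_year,colocated_with_referral,in_other_study
clinic_000,gov_b,86,0,0,0,0
clinic_001,gov_a,70,0,0,0,1
clinic_002,gov_c,115,0,0,1,0
clinic_003,gov_d,6,0,0,0,0
clinic_004,gov_e,35,0,0,0,1
clinic_005,gov_b,73,0,0,0,0
clinic_006,gov_c,30,0,0,0,0
clinic_007,gov_a,196,0,0,0,0
clinic_008,gov_a,87,0,0,1,0
clinic_009,gov_c,2,0,0,0,0
clinic_010,gov_a,154,0,0,0,0
clinic_011,gov_b,47,0,0,0,0
clinic_012,gov_b,108,0,0,1,0
clinic_013,gov_c,235,0,0,0,0
clinic_014,gov_d,34,0,0,0,0
clinic_015,gov_b,137,0,0,0,0
clinic_016,gov_b,0,0,1,0,0
clinic_017,gov_e,14,0,0,0,1
clinic_018,gov_a,58,0,0,0,0
clinic_019,gov_a,25,0,0,0,0
clinic_020,gov_e,0,0,1,0,0
clinic_021,gov_b,43,0,0,0,0
clinic_022,gov_c,56,0,0,0,0
clinic_023,gov_d,40,0,0,0,0
clinic_024,gov_e,16,0,0,0,0
clinic_025,gov_a,30,0,0,0,0
clinic_026,gov_c,33,0,0,0,0
clinic_027,gov_a,9,0,0,0,0
clinic_028,gov_d,153,0,0,0,0
clinic_029,gov_c,46,0,0,0,0
clinic_030,gov_b,24,0,0,0,1
clinic_031,gov_b,87,0,0,0,0
clinic_032,gov_a,13,0,0,0,1
clinic_033,gov_a,148,0,0,0,1
clinic_034,gov_d,53,0,0,0,0
clinic_035,gov_b,100,0,0,0,0
clinic_036,gov_a,212,0,0,0,0
clinic_037,gov_a,9,0,0,0,0
clinic_038,gov_c,152,0,0,0,0
clinic_039,gov_c,20,0,0,0,0
clinic_040,gov_e,25,0,0,0,0
clinic_041,gov_c,131,0,0,1,0
clinic_042,gov_d,110,0,0,0,0
clinic_043,gov_b,122,0,0,0,0
clinic_044,gov_a,15,0,0,0,0
clinic_045,gov_e,8,0,0,1,0
clinic_046,gov_b,398,0,0,0,0
clinic_047,gov_b,118,0,0,0,0
clinic_048,gov_c,34,0,0,0,0
clinic_049,gov_e,4,1,0,0,0
clinic_050,gov_b,85,0,0,0,0
clinic_051,gov_a,76,0,0,0,0
clinic_052,gov_e,52,0,0,0,0
clinic_053,gov_a,19,0,0,0,0
clinic_054,gov_a,9,0,0,1,0
clinic_055,gov_b,42,0,0,0,0
clinic_056,gov_c,54,0,0,0,0
clinic_057,gov_d,21,0,0,0,0
clinic_058,gov_c,42,0,0,0,0
clinic_059,gov_b,40,0,0,0,0
clinic_060,gov_a,56,0,0,0,0
clinic_061,gov_b,39,0,0,0,0
clinic_062,gov_d,16,0,0,0,0
clinic_063,gov_a,60,0,0,0,0
clinic_064,gov_b,78,0,0,1,0
clinic_065,gov_b,17,0,0,1,0
clinic_066,gov_c,60,0,0,0,0
clinic_067,gov_b,0,0,1,0,0
clinic_068,gov_d,36,0,0,0,0
clinic_069,gov_d,52,0,0,0,0
clinic_070,gov_a,70,0,0,0,0
clinic_071,gov_b,141,0,0,0,0
clinic_072,gov_c,27,0,0,0,0
clinic_073,gov_b,120,0,0,0,0
clinic_074,gov_c,12,0,0,0,0
clinic_075,gov_a,7,0,0,0,0
clinic_076,gov_c,104,0,0,0,0
clinic_077,gov_c,81,0,0,0,0
clinic_078,gov_c,55,0,0,1,0
clinic_079,gov_e,121,0,0,0,0
clinic_080,gov_a,46,0,0,0,0
clinic_081,gov_e,30,0,0,0,0
clinic_082,gov_d,29,0,0,0,0
clinic_083,gov_c,58,0,0,0,0
clinic_084,gov_a,0,0,1,0,0
clinic_085,gov_a,113,0,0,0,0
clinic_086,gov_c,140,0,0,0,0
clinic_087,gov_d,126,0,0,0,0
clinic_088,gov_d,185,0,0,0,0
clinic_089,gov_e,13,0,0,1,0
clinic_090,gov_e,13,0,0,0,0
clinic_091,gov_b,18,0,0,0,0
clinic_092,gov_b,15,0,0,0,0
clinic_093,gov_a,25,0,0,0,0
clinic_094,gov_b,6,0,0,0,0
clinic_095,gov_b,61,0,0,0,0
clinic_096,gov_a,5,1,0,0,0
clinic_097,gov_d,86,0,0,0,0
clinic_098,gov_c,94,0,0,0,1
clinic_099,gov_c,109,0,0,1,0
clinic_100,gov_b,27,0,0,0,0
clinic_101,gov_c,47,0,0,0,0
clinic_102,gov_a,101,0,0,0,0
clinic_103,gov_b,253,0,0,0,0
clinic_104,gov_a,20,0,0,0,0
clinic_105,gov_a,15,0,0,0,0
clinic_106,gov_c,63,0,0,0,0
clinic_107,gov_c,207,0,0,0,0
clinic_108,gov_b,104,0,0,1,0
clinic_109,gov_a,40,0,0,0,0
clinic_110,gov_a,38,0,0,0,0
clinic_111,gov_c,51,0,0,1,0
clinic_112,gov_e,55,0,0,0,0
clinic_113,gov_b,82,0,0,1,0
clinic_114,gov_c,49,0,0,0,0
clinic_115,gov_c,71,0,0,0,0
clinic_116,gov_c,130,0,0,1,0
clinic_117,gov_e,7,1,0,0,0
clinic_118,gov_a,9,0,0,0,0
clinic_119,gov_a,27,0,0,0,0
clinic_120,gov_c,19,0,0,0,0
clinic_121,gov_d,44,0,0,0,0
clinic_122,gov_c,5,0,0,0,0
clinic_123,gov_c,63,0,0,0,1
clinic_124,gov_c,72,0,0,0,0
clinic_125,gov_c,66,0,0,0,0
clinic_126,gov_c,63,0,0,1,0
clinic_127,gov_e,39,0,0,1,0
clinic_128,gov_e,0,0,1,0,0
clinic_129,gov_b,40,0,0,0,1
clinic_130,gov_d,29,0,0,1,0
clinic_131,gov_b,86,0,0,0,0
clinic_132,gov_e,88,0,0,0,0
clinic_133,gov_c,151,0,0,0,0
clinic_134,gov_c,107,0,0,0,0
clinic_135,gov_d,97,0,0,0,0
clinic_136,gov_b,101,0,0,0,1
clinic_137,gov_a,33,0,0,0,0
clinic_138,gov_a,26,0,0,0,0
clinic_139,gov_d,3,0,0,1,0
clinic_140,gov_e,2,0,0,0,0
clinic_141,gov_b,56,0,0,1,0
clinic_142,gov_b,147,0,0,0,0
clinic_143,gov_b,54,0,0,1,0
clinic_144,gov_a,174,0,0,0,0
clinic_145,gov_b,120,0,0,0,1
clinic_146,gov_a,126,0,0,0,0
clinic_147,gov_c,1,0,0,0,0
clinic_148,gov_b,10,0,0,0,0
clinic_149,gov_b,72,0,0,0,0
clinic_150,gov_d,37,0,0,0,0
clinic_151,gov_b,135,0,0,0,0
clinic_152,gov_c,100,0,0,1,0
clinic_153,gov_d,54,0,0,0,0
clinic_154,gov_d,98,0,0,0,0
clinic_155,gov_b,67,0,0,0,1
clinic_156,gov_a,39,0,0,0,0
clinic_157,gov_c,13,0,0,0,1
clinic_158,gov_d,30,0,0,0,0
clinic_159,gov_b,118,0,0,1,0
clinic_160,gov_d,57,0,0,0,0
clinic_161,gov_c,51,0,0,0,0
clinic_162,gov_e,19,0,0,0,0
clinic_163,gov_d,24,0,0,0,0
clinic_164,gov_a,27,0,0,0,0
clinic_165,gov_b,97,0,0,0,0
clinic_166,gov_a,137,0,0,0,0
clinic_167,gov_a,23,0,0,0,0
clinic_168,gov_a,165,0,0,0,0
clinic_169,gov_d,68,0,0,0,0
clinic_170,gov_c,2,1,0,0,0
clinic_171,gov_e,69,0,0,0,0
clinic_172,gov_d,1,0,0,0,0
clinic_173,gov_a,86,0,0,0,0
clinic_174,gov_c,81,0,0,0,0
clinic_175,gov_d,4,0,0,1,0
clinic_176,gov_c,3,1,0,0,0
clinic_177,gov_a,9,0,0,0,0
clinic_178,gov_d,55,0,0,0,0
clinic_179,gov_c,95,0,0,0,0
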
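pattern,pc_kcal,pa_kcal,feed_kcal,ec_g_per_kcal,ea_g_per_kcal,oi_ratio,fe_kcal,fossil_kg,et_kg
1,1727,146,268,0.82,12.48,14.1,141.8,0.05,3.51
2,1928,71,297,0.42,6.58,26.2,85.0,0.03,1.43
3,1904,114,278,1.81,4.30,26.6,82.0,0.03,4.46
4,1977,161,408,0.64,4.75,7.9,301.2,0.11,2.39
5,1885,273,511,0.50,3.25,3.6,675.5,0.24,2.34
6,1778,394,820,1.07,3.83,5.0,521.2,0.19,4.48
7,2078,133,445,0.57,13.06,8.1,312.3,0.11,3.29
8,2028,238,665,0.44,5.59,20.3,133.0,0.05,2.56
9,2149,386,138,,,,,,
10,2303,272,1061,0.37,2.37,2.1,1612.4,0.58,2.48
11,2240,465,1364,0.91,4.25,2.3,1603.8,0.58,5.85
12,2273,619,2681,0.32,2.02,2.2,2282.0,0.83,3.68
13,2613,442,1762,0.52,1.96,2.5,1775.5,0.64,3.78
14,2020,1090,3662,0.51,1.84,1.7,3313.2,1.20,6.10
15,2248,1052,5037,0.32,1.70,2.1,3490.9,1.26,5.37
16,2611,818,4701,0.31,1.44,2.1,3445.1,1.35,4.66
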
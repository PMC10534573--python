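run_id,A,B,C,D,E,F,G,H,J,K,L,P_imp_I,P_imp_II,P_API,P_imp_III,P_imp_IV,P_imp_V
1,39.5,1,76.5,16.5,1,10,-1,0.9,-1,35,229,1417.35,353.84,9069.79,418.65,281.58,1378.96
2,37.5,1,78.5,16,1,10,1,0.9,-1,25,231,1640.374,369.832,"10,040.28",405.841,238.698,1451.263
3,39.5,-1,78.5,16.5,-1,10,1,1.1,-1,25,229,1095.628,344.924,7130.304,254.497,212.253,1177.324
4,37.5,1,76.5,16.5,1,5,1,1.1,1,25,229,1051.206,264.087,6899.781,254.641,224.772,1053.161
5,37.5,-1,78.5,16,1,10,-1,1.1,1,35,229,1640.114,243.709,10624.03,408.023,283.986,1522.191
6,37.5,-1,76.5,16.5,-1,10,1,0.9,1,35,231,1301.494,361.236,8404.344,246.173,258.071,1176.329
7,39.5,-1,76.5,16,1,5,1,1.1,-1,35,231,1376.018,215.475,9289.761,203.823,221.739,1327.625
8,39.5,1,76.5,16,-1,10,-1,1.1,1,25,231,1084.411,325.384,6888.604,258.061,195.279,1093.397
9,39.5,1,78.5,16,-1,5,1,0.9,1,35,229,1768.829,306.912,"10,205.74",531.56,297.964,1532.409
10,37.5,1,78.5,16.5,-1,5,-1,1.1,-1,35,231,2001.457,289.047,9661.038,371.323,272.7,1340.322
11,39.5,-1,78.5,16.5,1,5,-1,0.9,1,25,231,1202.518,270.312,7721.945,269.349,229.951,1201.462
12,37.5,-1,76.5,16,-1,5,-1,0.9,-1,25,229,1625.379,400.925,10207.9,254.525,320.083,1531.502
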
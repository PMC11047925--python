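specimen,diameter_mm,sector,area_mm2,air_percent
1,66,PS-F,1239.78,5.91
1,66,SS-F,1038.92,8.85
1,66,AS-F,1020.50,0.93
1,66,SS-S,976.34,50.75
1,66,MS-S,1989.53,87.17
1,66,PS-A,338.73,1.84
1,66,MS-A,1723.69,81.38
1,66,AS-A,457.50,6.98
2,56,PS-F,1194.42,47.42
2,56,SS-F,1033.49,35.43
2,56,AS-F,1046.81,53.11
2,56,SS-S,1196.34,171.35
2,56,MS-S,1443.84,82.62
2,56,PS-A,369.56,28.61
2,56,MS-A,1569.34,136.47
2,56,AS-A,572.02,109.02
3,56,PS-F,963.31,36.53
3,56,SS-F,892.65,30.93
3,56,AS-F,1020.97,17.75
3,56,SS-S,494.59,5.15
3,56,MS-S,870.91,114.42
3,56,PS-A,320.26,4.02
3,56,MS-A,696.71,117.19
3,56,AS-A,273.66,0.00
4,52,PS-F,1039.78,43.09
4,52,SS-F,868.92,46.66
4,52,AS-F,680.50,8.43
4,52,SS-S,580.34,44.35
4,52,MS-S,989.53,49.97
4,52,PS-A,300.73,45.65
4,52,MS-A,829.69,40.64
4,52,AS-A,307.50,15.83
5,54,PS-F,1189.42,57.88
5,54,SS-F,1220.49,72.00
5,54,AS-F,867.81,36.51
5,54,SS-S,706.34,72.30
5,54,MS-S,1143.84,55.59
5,54,PS-A,469.56,75.74
5,54,MS-A,978.34,58.40
5,54,AS-A,332.02,30.48
6,58,PS-F,1363.31,80.12
6,58,SS-F,1642.65,124.61
6,58,AS-F,1220.97,31.28
6,58,SS-S,1194.59,136.76
6,58,MS-S,1830.91,124.25
6,58,PS-A,640.26,93.87
6,58,MS-A,1596.71,129.01
6,58,AS-A,433.66,47.72
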
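patient_id,compartment,bvtv,tb_th,tb_sp,tb_n,volume,mgv
1,femur,0.0716,0.2668,0.607,1.6402,243.5359,95.58
1,tibia,0.0495,0.219,0.7214,1.382,281.6452,75.22
2,femur,0.0623,0.2157,0.5647,1.7641,53.3224,77.21
2,tibia,0.0488,0.1985,0.6636,1.5024,287.4996,73.56
3,femur,0.1992,0.4619,0.3748,2.6356,381.7742,123.65
3,tibia,0.1721,0.3429,0.3226,3.0671,224.1293,105.45
4,femur,0.1068,0.331,0.5038,1.972,218.8271,92.33
4,tibia,0.1202,0.3831,0.5176,1.918,224.1203,115.49
5,femur,0.1349,0.3835,0.4613,2.15,259.8397,118.42
5,tibia,0.026,0.2197,1.3801,0.7234,81.4737,72.58
6,femur,0.1668,0.4955,0.481,2.058,267.7767,63.7
6,tibia,0.0912,0.3796,0.6769,1.4692,159.2747,58.9
7,femur,0.1429,0.468,0.531,1.8668,303.4012,121.36
7,tibia,0.1166,0.3813,0.5314,1.8684,216.5775,107.86
8,femur,0.1309,0.3129,0.3879,2.5571,224.0486,104.9
8,tibia,0.1593,0.3706,0.3769,2.6274,261.8792,106.39
9,femur,0.1626,0.448,0.4462,2.2189,276.8046,106.93
9,tibia,0.1293,0.3238,0.4066,2.4399,257.3116,61.54
10,femur,0.1578,0.3918,0.4023,2.4617,302.4606,54.38
10,tibia,0.1572,0.4298,0.443,2.2357,213.9549,87.11
11,femur,0.135,0.3787,0.4552,2.1789,172.3847,114.34
11,tibia,0.1265,0.3521,0.4517,2.1968,159.8268,92.82
12,femur,0.1176,0.3478,0.4804,2.0664,114.9964,55.24
12,tibia,0.2744,0.4114,0.2412,4.0759,289.7149,111.38
13,femur,0.1508,0.3358,0.361,2.7447,315.6059,59.48
13,tibia,0.0887,0.2583,0.4737,2.0994,86.5112,70.12
14,femur,0.1412,0.3514,0.4038,2.4552,285.6405,118.8
14,tibia,0.1417,0.3566,0.4081,2.429,207.508,54.64
15,femur,0.1533,0.3498,0.3698,2.6786,324.8141,50.76
15,tibia,0.1183,0.298,0.4093,2.4255,158.0593,88.3
16,femur,0.1279,0.41,0.5205,1.9062,389.4614,49.29
16,tibia,0.1428,0.2995,0.3402,2.9135,190.8696,90.49
17,femur,0.1209,0.3394,0.4558,2.1778,247.7926,97.41
17,tibia,0.1214,0.34,0.4548,2.1824,120.1776,104.01
18,femur,0.1171,0.414,0.5741,1.7294,246.2565,117.54
18,tibia,0.1204,0.355,0.4788,2.073,119.0466,118.83
19,femur,0.1431,0.3955,0.4483,2.2113,273.2562,94.3
19,tibia,0.1197,0.3505,0.4755,2.0878,195.7849,106.27
20,femur,0.1351,0.3647,0.4379,2.2648,306.7198,110.58
20,tibia,0.1339,0.349,0.423,2.3451,220.4959,102.66
21,femur,0.1295,0.3471,0.4351,2.2804,237.2063,103.88
21,tibia,0.1378,0.299,0.3517,2.8193,175.8877,91.23
22,femur,0.1539,0.4124,0.4341,2.2819,376.1578,124.65
22,tibia,0.128,0.349,0.4425,2.2422,235.0518,103.47
23,femur,0.1113,0.3052,0.4454,2.2298,112.3658,73.42
23,tibia,0.0712,0.2326,0.5322,1.8707,173.8293,97.27
24,femur,0.1384,0.3585,0.4201,2.3604,240.856,109.97
24,tibia,0.1256,0.336,0.4342,2.2854,150.8067,97.07
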
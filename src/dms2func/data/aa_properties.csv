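aa,prop_001,prop_002,prop_003,prop_004,prop_005,prop_006,prop_007,prop_008,prop_009,prop_010,prop_011,prop_012,prop_013,prop_014,prop_015,prop_016,prop_017,prop_018,prop_019,prop_020,prop_021,prop_022,prop_023,prop_024
A,38.8974,49.3751,-24.7607,-16.1355,-22.7461,-19.9068,-12.5495,-5.9905,-13.8064,4.8489,-49.2199,9.1196,-22.7582,1.1363,-33.8764,-22.0310,-14.1587,8.8435,-40.2901,-73.5004,-7.7373,2.8099,-2.2326,9.1058
C,40.8251,-5.0727,26.0313,-9.3532,79.1155,20.8904,29.8004,-25.6883,-16.2528,19.3197,-13.7290,38.5319,24.8376,10.5542,21.7918,25.6267,-5.4415,26.6128,0.3567,-36.4083,-6.4272,-2.1727,13.6913,52.2216
D,-1.7032,70.0623,9.3315,-2.0695,-33.2007,7.3429,25.6575,1.4403,5.2651,48.7415,48.2621,-2.1232,35.8707,3.8137,-13.6451,-33.2727,36.9221,-20.8026,2.7838,-66.7887,-2.1798,-2.1268,21.1766,43.2704
E,-33.6263,-35.7943,-20.3446,-16.0609,26.4594,-16.4637,18.9471,9.1913,18.9079,32.9649,45.0532,-13.7596,-31.5615,1.8919,-4.2032,-24.1404,28.6594,3.6269,25.5367,13.4778,-6.1305,9.5515,-66.0456,18.4607
F,-21.8371,21.3355,10.8878,-10.7027,76.2939,8.6408,-18.2941,5.4270,-5.0471,-0.7478,-19.2238,-8.1326,29.7771,-6.2937,-19.6821,-13.0827,-10.1878,43.1489,-3.1829,-16.8423,-7.2649,8.9809,-45.3171,0.4338
G,-49.0443,-35.1917,13.3915,0.0633,27.3052,11.1579,-2.6695,5.5232,10.5878,-19.1303,-2.8833,-8.1979,17.2321,5.2306,21.6871,-59.1054,-25.4424,14.1684,16.7467,24.4962,-6.9847,5.0278,-0.9303,-27.3934
H,-36.2070,-61.9518,-40.0113,-15.9626,-79.6371,-32.2911,62.9195,-19.3706,8.5583,19.2324,3.9276,29.1693,-41.6455,1.6250,-60.2346,-51.9255,-0.2710,-32.1565,1.8883,-31.5262,-6.6724,5.9349,-40.4814,27.0088
I,11.6201,-47.1515,-44.8497,-1.2358,34.2616,-35.3192,17.7277,-31.7279,-23.6991,2.1470,11.7892,47.5390,-5.7585,3.2520,13.5269,-4.1042,-12.2352,-7.1425,-4.6612,-41.7022,-7.5165,-6.0803,-126.7842,2.7176
K,5.0557,-45.6935,-14.8358,-12.8902,-31.8605,-11.8821,-71.1419,2.3200,-3.1577,-10.2832,-10.4874,-3.5606,-9.4508,15.1054,-4.1893,-57.4928,-22.4787,-16.0247,-19.9115,39.3908,-7.9820,-1.4429,-22.6248,-6.0168
L,-11.6290,-22.3681,9.2154,-7.2514,-52.4013,7.2200,19.9151,-24.7944,-11.1253,48.1073,-4.9188,37.2030,73.5626,4.7123,45.1861,12.7156,-0.3113,18.8701,5.1133,32.8378,-7.6513,-2.7629,0.6374,39.9928
M,-46.8734,-19.2847,-57.2270,-13.5597,-0.1112,-45.9009,-71.1748,-19.1934,-9.1478,-9.2016,-6.7388,28.9029,12.9693,6.9572,-13.8040,67.2794,-10.3127,-2.6374,37.8134,-42.9298,-4.5684,-8.6799,-44.7083,-9.9840
N,2.7836,-36.7732,8.3451,-5.7428,-26.3076,6.8487,58.2953,-12.2820,18.7836,-41.5792,-11.1432,18.5301,12.3406,6.9538,-26.9348,-44.6565,-10.0819,4.0833,27.7952,-91.9201,-8.1839,2.4199,-52.5359,4.4159
P,53.3624,-30.1508,-7.6930,-27.5291,-58.6248,-6.2411,7.7967,-2.6205,1.2096,-39.7567,38.7704,3.8643,-66.9932,4.0290,17.5914,15.9075,-37.9715,-27.5857,1.8274,9.8049,-9.7380,6.7070,-3.3589,-9.2194
Q,-39.7617,-14.2041,-41.0082,4.5044,-29.3451,-32.6785,-60.3055,4.9255,8.2563,-23.9115,-9.7282,-7.4144,-7.7871,4.3223,13.3469,-26.7771,-37.0885,-34.7297,-8.0628,-6.7611,-8.8970,2.7844,-34.9399,-32.0617
R,15.4860,62.1994,-21.9969,-5.8806,23.3821,-17.7200,-62.4761,-24.2159,-13.5560,25.1420,18.5915,36.1352,59.5962,8.1083,-36.6452,-10.3869,-50.1378,3.6388,35.3098,-20.4124,-7.6509,1.3134,2.1821,10.8869
S,-27.8169,-0.5836,-26.6549,-12.3962,43.7715,-21.1882,-18.6583,-0.7824,-3.8681,15.7741,-41.1308,0.9954,12.9659,4.7260,11.1048,-78.5587,-16.2044,11.2729,-9.2411,-19.1908,-9.8309,2.2553,39.6462,-34.6056
T,15.2968,-21.5028,-26.6518,-7.0374,17.5735,-21.4389,-1.6564,-14.0817,-12.8720,-15.6625,-33.6955,21.1021,-61.5637,7.7425,-31.8138,37.5221,-25.5844,21.5231,9.2398,-60.5875,-4.8174,6.5753,6.2249,-16.2465
V,-2.9418,12.2348,-57.6072,-6.9891,-11.5681,-46.1888,-23.7662,-6.6302,4.3015,-1.8433,18.2179,9.8957,-48.1488,1.1202,-28.4038,-6.5403,-2.1147,6.6371,19.0087,34.1147,-8.7055,8.7772,27.5960,-31.5901
W,-7.6449,12.5563,-2.1519,-2.4917,-93.9451,-1.7936,-4.7709,-17.9589,-12.4965,39.3826,40.5029,26.9722,-17.1443,-0.1148,-59.4168,45.5793,36.9373,-7.3391,-6.6434,-23.1699,-7.2276,-10.4456,7.0148,22.9344
Y,-44.6796,29.7703,42.8287,-3.9065,26.2270,34.1190,29.3607,-7.8926,-22.3602,-24.4312,81.6171,12.0070,7.8933,0.1658,-41.4838,-64.5836,-5.2969,23.1549,-4.2534,-17.2994,-6.5164,-2.7849,-8.0879,37.0423
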
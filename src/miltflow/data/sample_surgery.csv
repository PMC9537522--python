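procedure_id,method,treatment_type,level,entity,start_s,end_s,parallel,note
OUH-PS-S56,LLR,atypical,meta,total_s,0,4203,false,
OUH-PS-S56,LLR,atypical,phase,P06,0,7,false,
OUH-PS-S56,LLR,atypical,module,P06.M01,0,7,false,
OUH-PS-S56,LLR,atypical,phase,P05,7,89,false,
OUH-PS-S56,LLR,atypical,module,P05.M02,7,89,false,
OUH-PS-S56,LLR,atypical,phase,P06,89,95,false,
OUH-PS-S56,LLR,atypical,module,P06.M01,89,95,false,
OUH-PS-S56,LLR,atypical,phase,P07,100,135,false,
OUH-PS-S56,LLR,atypical,module,P07.M01,100,135,false,
OUH-PS-S56,LLR,atypical,phase,P07,135,155,false,
OUH-PS-S56,LLR,atypical,module,P07.M01,135,155,false,
OUH-PS-S56,LLR,atypical,phase,P06,155,161,false,
OUH-PS-S56,LLR,atypical,module,P06.M01,155,161,false,
OUH-PS-S56,LLR,atypical,phase,P07,165,185,false,
OUH-PS-S56,LLR,atypical,module,P07.M01,165,185,false,
OUH-PS-S56,LLR,atypical,phase,P07,185,199,false,
OUH-PS-S56,LLR,atypical,module,P07.M01,185,199,false,
OUH-PS-S56,LLR,atypical,phase,P08a,210,1525,false,
OUH-PS-S56,LLR,atypical,module,P08a.M01,210,300,false,
OUH-PS-S56,LLR,atypical,module,P08a.M02,300,818,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,818,858,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,858,898,false,
OUH-PS-S56,LLR,atypical,module,P08a.M05,898,955,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,955,995,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,995,1045,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1045,1085,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,1085,1131,false,
OUH-PS-S56,LLR,atypical,module,P08a.M05,1131,1181,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,1181,1227,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1227,1267,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,1267,1313,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1313,1353,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,1353,1399,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1399,1439,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,1439,1485,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1485,1525,false,
OUH-PS-S56,LLR,atypical,phase,P10,1545,1716,false,
OUH-PS-S56,LLR,atypical,module,P10.M01,1545,1716,false,
OUH-PS-S56,LLR,atypical,phase,P11,1726,1866,false,
OUH-PS-S56,LLR,atypical,module,P11.M02,1726,1866,false,
OUH-PS-S56,LLR,atypical,phase,P08a,1896,3115,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1896,1937,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1937,1978,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,1978,2018,false,
OUH-PS-S56,LLR,atypical,module,P08a.M05,2018,2072,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2072,2111,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2111,2150,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2150,2189,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2189,2228,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2228,2268,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2268,2308,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2308,2348,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2348,2388,false,
OUH-PS-S56,LLR,atypical,module,P08a.M05,2388,2441,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2441,2480,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2480,2518,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2518,2556,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2556,2594,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2594,2632,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2632,2672,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2672,2712,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2712,2752,false,
OUH-PS-S56,LLR,atypical,module,P08a.M05,2752,2805,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2805,2843,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2843,2881,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,2881,2919,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2919,2959,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2959,2999,false,
OUH-PS-S56,LLR,atypical,module,P08a.M03,2999,3039,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,3039,3077,false,
OUH-PS-S56,LLR,atypical,module,P08a.M06,3077,3115,false,
OUH-PS-S56,LLR,atypical,phase,P10,3140,3378,false,
OUH-PS-S56,LLR,atypical,module,P10.M02,3140,3378,false,
OUH-PS-S56,LLR,atypical,phase,P10,3380,3618,false,
OUH-PS-S56,LLR,atypical,module,P10.M02,3380,3618,false,
OUH-PS-S56,LLR,atypical,phase,P06,3618,3625,false,
OUH-PS-S56,LLR,atypical,module,P06.M01,3618,3625,false,
OUH-PS-S56,LLR,atypical,phase,P13,3675,4203,false,
OUH-PS-S56,LLR,atypical,module,P13.M04,3675,3715,false,
OUH-PS-S56,LLR,atypical,module,P13.M06,3715,3765,false,
OUH-PS-S56,LLR,atypical,module,P13.M02,3765,3841,false,
OUH-PS-S56,LLR,atypical,module,P13.M04,3841,3881,false,
OUH-PS-S56,LLR,atypical,module,P13.M06,3881,3941,false,
OUH-PS-S56,LLR,atypical,module,P13.M03,3941,4062,false,
OUH-PS-S56,LLR,atypical,module,P13.M04,4062,4094,false,
OUH-PS-S56,LLR,atypical,module,P13.M06,4094,4154,false,
OUH-PS-S56,LLR,atypical,module,P13.M06,4154,4203,false,
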
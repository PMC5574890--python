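forest,code,climate,forest_type,stand_age,logging_maturity_age,corrected_maturity_age,initial_year,final_year,n_years,NEP_trend,NEP_se,NEP_p,GPP_trend,GPP_se,GPP_p,Re_trend,Re_se,Re_p,LAI_trend,LAI_se,LAI_p
Brasschaat,BE-Bra,Temp,M,80,90,0.89,1997,2011,14,17.5,7.5,0.0773,21.4,13.9,0.0313,9.7,19.8,0.2556,0.000,0.008,0.6329
Castelporziano,IT-Cpz,Temp,EB,61,75,0.81,1997,2008,10,2.8,6.9,0.3603,-12.8,16.9,0.7629,-22.1,12.8,0.8145,0.100,0.010,0.0173
Collelongo,IT-Col,Temp,DB,118,95,1.24,1997,2012,12,4.1,9.6,0.2686,16.8,11.9,0.1219,8.5,6.4,0.0574,-0.014,0.015,0.8299
Hainich,DE-Hai,Temp,DB,275,95,2.89,2000,2012,13,-7.3,4.6,0.9197,-11.2,7.3,0.8502,-6.3,5.9,0.7489,0.047,0.018,0.0466
Harvard,US-Ha1,Temp,DB,81,75,1.07,1992,2011,20,12.6,5.9,0.0372,34.7,5.1,0.0001,20.2,9.6,0.0075,0.000,0.005,0.6539
Hesse,FR-Hes,Temp,DB,43,95,0.45,1996,2010,15,26.4,11.0,0.0374,18.3,15.4,0.1381,0.5,15.3,0.5000,0.017,0.007,0.2737
Howland MT,US-Ho1,Temp,EC,109,90,1.21,1996,2008,13,6.5,2.8,0.0293,-5.8,7.5,0.7489,-16.2,7.2,0.9364,-0.050,0.008,0.9934
Howland F,US-Ho2,Temp,EC,109,90,1.21,1999,2009,11,5.4,4.8,0.1751,7.7,8.2,0.2667,2.6,11.0,0.3202,-0.025,0.011,0.7621
Hyytiala,FI-Hyy,Bor,EC,47,90,0.52,1997,2012,16,6.2,2.5,0.0172,14.7,4.0,0.0017,10.4,3.5,0.0051,0.000,0.004,0.5201
Lavarone,IT-Lav,Temp,EC,120,90,1.33,2003,2012,10,41.8,10.3,0.0100,37.2,12.8,0.0159,-2.7,5.1,0.7042,0.114,0.022,0.1008
Le Bray,FR-LBr,Temp,EC,38,90,0.42,1997,2008,11,7.2,18.8,0.4381,10.8,25.6,0.3777,-18.3,12.6,0.8935,-0.033,0.014,0.8465
Loobos,NL-Loo,Temp,EC,88,90,0.98,1997,2012,16,21.5,4.9,0.0009,-6.0,4.2,0.9186,-27.1,5.9,0.9991,-0.017,0.008,0.6559
Metolius,US-Me2,Temp,EC,64,90,0.71,2002,2012,11,13.4,9.8,0.1379,29.0,13.7,0.0806,10.6,13.4,0.2667,0.156,0.028,0.0866
Morgan Monroe,US-MMS,Temp,DB,70,75,0.93,1999,2013,15,-2.6,3.9,0.8619,-1.8,5.5,0.6897,0.7,5.0,0.5000,-0.041,0.009,0.8677
Niwot ridge,US-NR1,Bor,EC,98,90,1.09,1999,2010,12,1.9,2.8,0.4185,-0.1,3.4,0.5000,-1.3,2.3,0.6341,0.060,0.005,0.0166
Park Falls,US-PFa,Temp,DB,44,65,0.68,1997,2013,16,9.6,3.7,0.0172,0.1,4.3,0.4820,-12.1,6.2,0.9425,-0.008,0.008,0.5873
Puechabon,FR-Pue,Temp,EB,66,75,0.88,2001,2013,13,-10.3,6.6,0.9197,-28.4,13.3,0.9502,-18.5,8.7,0.9880,0.114,0.014,0.0108
Renon,IT-Ren,Bor,EC,90,75,1.20,1998,2011,13,37.9,5.3,0.0001,51.9,8.7,0.0006,10.2,6.3,0.0636,0.030,0.007,0.1202
Sodankyla,FI-Sod,Bor,EC,75,90,0.83,2000,2012,13,-0.2,1.6,0.5000,-2.8,7.1,0.5243,0.6,6.8,0.4757,0.047,0.005,0.1346
Soroe,DK-Sor,Temp,DB,78,95,0.82,1997,2009,13,27.3,4.8,0.0004,22.9,8.4,0.0164,-0.2,8.8,0.5000,-0.017,0.007,0.7336
Tharandt,DE-Tha,Temp,EC,117,90,1.30,1997,2013,17,-1.2,3.6,0.6446,16.1,8.3,0.0383,20.4,6.7,0.0178,-0.025,0.014,0.6730
UMBS,US-UMB,Temp,DB,79,65,1.22,1999,2012,14,5.4,3.1,0.0080,-3.5,5.4,0.7444,-10.4,4.5,0.9373,0.058,0.005,0.0017
Vielsalm,BE-Vie,Temp,M,83,95,0.87,1996,2008,13,17.0,6.9,0.0062,15.1,6.8,0.0120,-0.3,7.2,0.5243,,,0.2330
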
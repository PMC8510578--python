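figure,experiment,genotype,n_larvae,approach_pre,avoid_pre,approach_post,avoid_post,approach_next_day,avoid_next_day
1B,Gr63a1,Gr63a1,44,831,745,,,,
1B,DANi1>CsChrimson ATR+,DANi1>CsChrimson,159,1714,4978,,,,
1B,DANi1>CsChrimson ATR-,DANi1>CsChrimson,16,256,614,,,,
1D,Paired,DANi1>CsChrimson,64,561,1760,936,868,,
1D,Offset After,DANi1>CsChrimson,20,288,757,316,305,,
1D,Reverse Paired,DANi1>CsChrimson,29,315,1022,154,530,,
1D,Offset Before,DANi1>CsChrimson,19,218,512,136,315,,
1D,Paired ATR-,DANi1>CsChrimson,16,256,614,127,307,,
1D,No Training,DANi1>CsChrimson,50,578,1599,479,1295,,
1D,DAN w/o CO2,DANi1>CsChrimson,16,260,597,161,354,,
1D,Driver ctrl,SS00864,17,110,289,158,358,,
1D,Effector ctrl,UAS-CsChrimson,18,214,516,114,294,,
1D,58E02>CsChrimson,58E02>CsChrimson,21,380,912,493,501,,
1E,Forward Paired,DANi1>CsChrimson,22,181,496,350,337,,
1E,Backwards Paired,DANi1>CsChrimson,18,181,438,124,320,,
1E,Btw CO2,DANi1>CsChrimson,23,272,652,165,283,,
1F,6.5%,DANi1>CsChrimson,19,361,568,319,290,,
1F,8%,DANi1>CsChrimson,27,256,567,295,255,,
1F,15%,DANi1>CsChrimson,19,170,368,249,233,,
1F,18%,DANi1>CsChrimson,64,561,1760,936,868,,
2,0 Cycles,DANi1>CsChrimson,50,578,1599,479,1295,,
2,1 Cycles,DANi1>CsChrimson,35,218,606,317,495,,
2,2 Cycles,DANi1>CsChrimson,87,840,2552,1081,1292,,
2,3 Cycles,DANi1>CsChrimson,31,310,930,686,686,,
2,4 Cycles,DANi1>CsChrimson,32,245,712,493,511,,
2,5 Cycles,DANi1>CsChrimson,63,863,2491,975,993,,
2,10 Cycles,DANi1>CsChrimson,14,100,287,154,144,,
2,20 Cycles,DANi1>CsChrimson,64,561,1760,936,868,,
3,"2 Cycles, Training",DANi1>CsChrimson,87,840,2552,1081,1292,,
3,"2 Cycles, Habituation + Training",DANi1>CsChrimson,30,385,1127,422,554,,
3,"2 Cycles, Training + Extinction",DANi1>CsChrimson,30,336,946,375,793,,
3,"3 Cycles, Training",DANi1>CsChrimson,30,308,924,675,679,,
3,"3 Cycles, Habituation + Training",DANi1>CsChrimson,18,222,591,260,294,,
3,"3 Cycles, Training + Extinction",DANi1>CsChrimson,26,279,695,195,416,,
3,"4 Cycles, Training",DANi1>CsChrimson,30,225,659,490,502,,
3,"4 Cycles, Habituation + Training",DANi1>CsChrimson,18,239,701,372,352,,
3,"4 Cycles, Training + Extinction",DANi1>CsChrimson,27,384,1074,394,475,,
3,"5 Cycles, Training",DANi1>CsChrimson,63,863,2491,975,993,,
3,"6 Cycles, Habituation + Training",DANi1>CsChrimson,19,266,758,367,324,,
3,"6 Cycles, Training + Extinction",DANi1>CsChrimson,18,253,687,309,317,,
3,"10 Cycles, Training",DANi1>CsChrimson,14,100,287,154,144,,
3,"10 Cycles, Habituation + Training",DANi1>CsChrimson,30,406,1193,607,503,,
3,"10 Cycles, Training + Extinction",DANi1>CsChrimson,30,426,1180,401,386,,
4B,20x,DANi1>CsChrimson,28,380,1172,509,499,459,409
4B,20x (Only Test Next Day),DANi1>CsChrimson,14,224,768,,,296,250
4B,5x,DANi1>CsChrimson,29,472,1427,488,480,404,461
4B,2x,DANi1>CsChrimson,42,514,1537,594,693,201,548
4B,2x (Only Test Next Day),DANi1>CsChrimson,22,209,696,,,213,283
4B,No Train,DANi1>CsChrimson,20,316,889,187,544,104,337
4B,RP 20x,DANi1>CsChrimson,21,282,905,121,430,109,361
4B,Ext Post-Train,DANi1>CsChrimson,23,181,477,,,158,365
4B,Ext Pre-Test,DANi1>CsChrimson,31,417,1002,,,385,429
4C,M 20x (CXM+/ATR+),DANi1>CsChrimson,20,110,282,252,237,237,272
4C,M 20x (CXM-/ATR+),DANi1>CsChrimson,17,159,419,271,236,228,235
4C,S 20x (CXM+/ATR+),DANi1>CsChrimson,23,191,486,,,150,316
4C,S 20x (CXM-/ATR+),DANi1>CsChrimson,20,197,511,,,254,264
4C,M 10x (CXM+/ATR+),DANi1>CsChrimson,23,136,345,,,331,344
4C,M 10x (CXM-/ATR+),DANi1>CsChrimson,20,175,454,,,419,375
4D,M 10x HS,DANi1>hs-dCREB2-b;CsChrimson,21,175,434,392,370,253,246
4D,M 10x No HS,DANi1>hs-dCREB2-b;CsChrimson,22,248,656,367,353,451,490
4D,S 10x HS,DANi1>hs-dCREB2-b;CsChrimson,24,172,420,68,156,153,339
4D,S 10x No HS,DANi1>hs-dCREB2-b;CsChrimson,22,294,736,212,184,335,352
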
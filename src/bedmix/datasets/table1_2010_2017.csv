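region,ward,year,beds,discharges,inpatient_days
Abruzzo,all,2010,3688,140355,1044054
Basilicata,all,2010,1723,61958,464549
Calabria,all,2010,4231,170137,1156658
Campania,all,2010,11423,485809,3228706
Emilia Romagna,all,2010,14278,526436,4231655
Friuli Venezia Giulia,all,2010,3931,132046,1092524
Lazio,all,2010,16472,600001,4905223
Liguria,all,2010,5775,198075,1738658
Lombardia,all,2010,30216,1085883,8644011
Marche,all,2010,4802,177308,1349109
Molise,all,2010,1335,48710,370750
Piemonte,all,2010,13175,443031,3984466
P.A. Bolzano,all,2010,1660,66503,467972
P.A. Trento,all,2010,1756,50846,439402
Puglia,all,2010,11971,488098,3376215
Sardegna,all,2010,4834,181711,1288677
Sicilia,all,2010,11348,476575,3287241
Toscana,all,2010,10719,431772,2960213
Umbria,all,2010,2521,117888,777688
Valle d'Aosta,all,2010,401,14340,119400
Veneto,all,2010,16236,527677,4735739
Abruzzo,all,2017,2966,118111,902896
Basilicata,all,2017,1654,57352,446263
Calabria,all,2017,3168,129178,923884
Campania,all,2017,9899,389661,2827162
Emilia Romagna,all,2017,12808,493810,3753721
Friuli Venezia Giulia,all,2017,3504,132105,1011899
Lazio,all,2017,14213,489919,4016779
Liguria,all,2017,4847,177825,1507474
Lombardia,all,2017,28047,952930,7956351
Marche,all,2017,3969,145161,1151105
Molise,all,2017,1063,33597,263986
Piemonte,all,2017,11604,381420,3394503
P.A. Bolzano,all,2017,1578,61154,445617
P.A. Trento,all,2017,1353,51594,400525
Puglia,all,2017,9306,373040,2751312
Sardegna,all,2017,4139,152247,1120080
Sicilia,all,2017,10200,365911,3043748
Toscana,all,2017,9139,372440,2603535
Umbria,all,2017,2565,102723,782340
Valle d'Aosta,all,2017,379,13506,108196
Veneto,all,2017,14638,500422,4244400
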
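region,ward,year,beds,discharges,inpatient_days
Abruzzo,intensive_care,2010,91,1105,18566
Basilicata,intensive_care,2010,41,698,10576
Calabria,intensive_care,2010,107,1666,24931
Campania,intensive_care,2010,363,7239,94649
Emilia Romagna,intensive_care,2010,372,3710,53817
Friuli Venezia Giulia,intensive_care,2010,103,1743,14424
Lazio,intensive_care,2010,510,4770,98347
Liguria,intensive_care,2010,173,1843,28332
Lombardia,intensive_care,2010,663,6775,92057
Marche,intensive_care,2010,113,1608,18885
Molise,intensive_care,2010,29,413,6930
Piemonte,intensive_care,2010,316,3428,50239
P.A. Bolzano,intensive_care,2010,36,616,7205
P.A. Trento,intensive_care,2010,20,272,2673
Puglia,intensive_care,2010,197,3891,53895
Sardegna,intensive_care,2010,107,1614,25445
Sicilia,intensive_care,2010,336,5240,73888
Toscana,intensive_care,2010,322,3415,49959
Umbria,intensive_care,2010,61,683,8615
Valle d'Aosta,intensive_care,2010,8,118,911
Veneto,intensive_care,2010,448,4851,68142
Abruzzo,intensive_care,2017,92,1198,17723
Basilicata,intensive_care,2017,49,745,9782
Calabria,intensive_care,2017,124,2741,29237
Campania,intensive_care,2017,427,6502,91616
Emilia Romagna,intensive_care,2017,360,4201,51943
Friuli Venezia Giulia,intensive_care,2017,119,1936,16132
Lazio,intensive_care,2017,486,4699,91136
Liguria,intensive_care,2017,164,1491,25157
Lombardia,intensive_care,2017,738,7641,91661
Marche,intensive_care,2017,127,1538,19826
Molise,intensive_care,2017,35,496,6980
Piemonte,intensive_care,2017,299,3468,44595
P.A. Bolzano,intensive_care,2017,37,612,4592
P.A. Trento,intensive_care,2017,31,369,3628
Puglia,intensive_care,2017,231,3884,56404
Sardegna,intensive_care,2017,120,1695,22436
Sicilia,intensive_care,2017,323,5118,76188
Toscana,intensive_care,2017,373,3911,56092
Umbria,intensive_care,2017,69,730,8914
Valle d'Aosta,intensive_care,2017,10,118,1273
Veneto,intensive_care,2017,468,4777,64813
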
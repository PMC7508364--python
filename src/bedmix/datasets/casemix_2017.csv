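region,ward,year,cmi,pi
Abruzzo,all,2017,1.02,0.97
Basilicata,all,2017,1.03,0.97
Calabria,all,2017,0.95,0.98
Campania,all,2017,0.94,0.99
Emilia Romagna,all,2017,1.02,0.96
Friuli Venezia Giulia,all,2017,1.01,1.00
Lazio,all,2017,0.96,1.08
Liguria,all,2017,1.08,1.01
Lombardia,all,2017,1.03,1.04
Marche,all,2017,0.96,1.06
Molise,all,2017,1.03,1.02
Piemonte,all,2017,1.03,1.10
P.A. Bolzano,all,2017,0.99,0.93
P.A. Trento,all,2017,1.01,0.98
Puglia,all,2017,0.95,0.99
Sardegna,all,2017,0.97,1.05
Sicilia,all,2017,0.97,1.08
Toscana,all,2017,1.00,0.91
Umbria,all,2017,1.04,0.94
Valle d'Aosta,all,2017,1.02,1.08
Veneto,all,2017,1.03,1.04
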
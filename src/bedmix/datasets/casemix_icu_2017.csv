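region,ward,year,cmi,pi
Abruzzo,intensive_care,2017,0.97,1.14
Basilicata,intensive_care,2017,1.25,1.02
Calabria,intensive_care,2017,2.05,0.81
Campania,intensive_care,2017,1.58,1.04
Emilia Romagna,intensive_care,2017,0.81,0.91
Friuli Venezia Giulia,intensive_care,2017,1.39,0.62
Lazio,intensive_care,2017,0.91,1.42
Liguria,intensive_care,2017,0.80,1.24
Lombardia,intensive_care,2017,0.76,0.88
Marche,intensive_care,2017,1.01,0.95
Molise,intensive_care,2017,1.41,1.14
Piemonte,intensive_care,2017,0.86,0.95
P.A. Bolzano,intensive_care,2017,0.96,0.60
P.A. Trento,intensive_care,2017,0.68,0.75
Puglia,intensive_care,2017,0.98,1.08
Sardegna,intensive_care,2017,1.05,0.98
Sicilia,intensive_care,2017,1.33,1.09
Toscana,intensive_care,2017,1.00,1.05
Umbria,intensive_care,2017,0.67,0.91
Valle d'Aosta,intensive_care,2017,0.85,0.87
Veneto,intensive_care,2017,0.90,1.00
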
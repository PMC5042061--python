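lake_id,latitude,longitude,area,duration,pct_endemism,distance,n_species,mean_beta
Bresse,46.641,5.243,9651.04,1.80,17.19,28,64,0.540
Caspian Sea,41.808,50.513,378666.31,0.88,92.39,207,92,0.528
Dacia,45.132,26.295,98730.88,6.00,56.44,30,303,0.551
Drnis,43.836,16.263,24.89,0.70,16.28,12,43,0.638
Gacko,43.140,18.544,39.57,0.60,0.00,60,12,0.502
Granada,37.110,-3.832,931.43,1.70,0.00,50,21,0.500
Groisenbach,47.543,15.270,22.63,0.20,91.67,40,12,0.728
Kosovo,42.590,21.066,920.44,1.30,27.27,12,22,0.584
Kupres,43.986,17.215,65.40,0.40,30.43,30,23,0.445
Le Locle,47.074,6.779,11.38,0.50,5.56,13,18,0.413
Metohia,42.501,20.544,1805.05,3.45,70.93,12,86,0.565
Nordlinger Ries,48.885,10.564,438.24,1.20,16.67,5,6,0.490
Ohrid,41.037,20.716,356.37,1.50,64.71,9,68,0.409
Pamvotis,39.663,20.884,22.70,0.40,12.00,95,25,0.481
Pannon,46.491,20.340,233485.79,7.10,74.61,55,579,0.435
Randeck Maar,48.576,9.526,1.08,0.30,0.00,13,4,0.607
Sinj,43.695,16.682,131.80,3.00,39.66,12,58,0.556
Slavonia,45.404,18.765,24243.25,2.50,44.24,125,165,0.545
Sofia,42.732,23.385,908.40,1.50,16.67,96,6,0.493
Sostanj,46.382,15.071,13.87,0.50,66.67,67,9,0.503
Steinheim,48.686,10.070,7.32,1.20,47.62,10,42,0.474
Transylvania,45.840,25.751,2221.12,3.00,53.85,30,78,0.579
Trichonis,38.559,21.552,94.83,2.60,13.04,3,23,0.549
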
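cluster,keyword,freq,overall_degree,network_strength,centroid_distance,octant
1,Mental health,7,11,4.195,2.019,Core emerging hotspot
1,Big data,6,10,3.829,1.903,Potential breakthrough theme
1,Public health,6,24,9.121,0.872,Core emerging hotspot
1,Depression,3,5,1.722,2.099,Peripheral mature theme
1,Google trend,3,7,2.460,1.330,Peripheral mature theme
1,Perception,3,15,5.166,1.918,Potential breakthrough theme
1,Cyberincivility,2,3,1.705,1.758,Exploratory emerging theme
1,Digital health,2,3,1.199,1.822,Peripheral emerging theme
1,Drug repositioning,2,6,0.983,2.100,Exploratory emerging theme
1,LSTM,2,7,2.198,0.980,Peripheral emerging theme
1,Medium,2,1,0.492,0.989,Peripheral obsolete theme
1,Neoplasms,2,5,1.979,1.688,Exploratory emerging theme
1,Nurse,2,6,2.240,1.669,Peripheral emerging theme
1,Republic of Korea,2,3,0.944,1.542,Exploratory emerging theme
1,Social networking site,2,3,1.705,1.661,Exploratory emerging theme
1,Suicide,2,4,1.426,2.450,Peripheral emerging theme
1,Thematic analysis,2,6,2.165,1.401,Exploratory emerging theme
1,Web scraping,2,3,0.757,1.685,Exploratory emerging theme
1,YouTube,2,3,1.127,1.599,Exploratory emerging theme
2,Natural language processing,36,41,13.465,0.752,Core emerging hotspot
2,Social media mining,24,27,8.489,0.067,Core emerging hotspot
2,Machine learning,22,28,8.820,0.473,Core emerging hotspot
2,Pharmacovigilance,9,8,2.776,0.511,Peripheral mature theme
2,Information storage and retrieval,5,6,2.311,0.511,Exploratory emerging theme
2,Drug-related side effects and adverse reactions,4,6,1.841,0.404,Peripheral emerging theme
2,Rare disease,3,4,1.080,0.452,Peripheral obsolete theme
2,Computational social science,2,2,0.360,0.551,Exploratory emerging theme
2,Epidemiology,2,4,1.285,0.788,Peripheral obsolete theme
2,Patient forum,2,5,1.318,0.469,Exploratory emerging theme
2,Patient-reported outcome measures,2,6,1.959,0.840,Exploratory emerging theme
2,Post-acute COVID-19 syndrome,2,5,1.755,0.925,Exploratory emerging theme
2,Psychological,2,3,0.786,1.153,Peripheral emerging theme
2,Quality of life,2,1,0.181,0.507,Exploratory emerging theme
2,Symptom,2,5,2.282,0.939,Exploratory emerging theme
3,Pandemics,9,23,8.704,0.567,Core emerging hotspot
3,Vaccination,6,18,7.074,0.347,Core emerging hotspot
3,Vaccination hesitancy,4,7,2.706,0.163,Peripheral emerging theme
3,Attitude,3,14,5.578,0.340,Potential breakthrough theme
3,SARS-CoV-2,3,13,5.132,0.150,Potential breakthrough theme
3,Human,2,4,1.927,0.480,Exploratory emerging theme
3,Influenza,2,4,1.927,0.480,Exploratory emerging theme
3,Twitter mining,2,4,1.447,0.411,Exploratory emerging theme
4,COVID-19,43,49,16.294,0.326,Core emerging hotspot
4,Twitter,34,37,13.168,0.829,Core emerging hotspot
4,Infodemiology,14,25,8.831,0.220,Core emerging hotspot
4,Topic modeling,10,18,6.685,0.678,Core emerging hotspot
4,Coronavirus,8,13,5.151,0.173,Core emerging hotspot
4,Tweet,6,15,5.508,0.603,Immature but declining theme
4,Public opinion,4,5,1.906,0.800,Exploratory emerging theme
4,Communicable diseases,3,4,1.704,0.291,Peripheral mature theme
4,Internet,3,5,2.005,0.673,Peripheral mature theme
4,Communication,2,7,2.648,0.245,Exploratory emerging theme
4,Electronic nicotine delivery systems,2,4,1.250,0.668,Peripheral obsolete theme
4,Geolocation,2,6,1.965,0.770,Exploratory emerging theme
4,Neural network,2,6,2.124,0.273,Exploratory emerging theme
5,Content analysis,5,28,10.239,0.354,Potential breakthrough theme
5,Facebook,5,10,2.980,0.519,Exploratory emerging theme
5,Adolescent,3,9,3.117,0.618,Exploratory emerging theme
5,Association rule mining,3,7,2.490,0.518,Exploratory emerging theme
5,Health communication,2,3,1.296,0.175,Exploratory emerging theme
5,Health promotion,2,5,1.930,0.876,Exploratory emerging theme
5,Smoking,2,9,2.878,0.387,Exploratory emerging theme
5,Social media analysis,2,6,1.984,0.450,Exploratory emerging theme
5,Tobacco,2,8,2.620,0.498,Exploratory emerging theme
5,User engagement,2,3,1.255,0.311,Exploratory emerging theme
6,Sentiment analysis,25,21,7.476,0.462,Core emerging hotspot
6,Deep learning,9,15,5.526,0.351,Potential breakthrough theme
6,Latent Dirichlet allocation,6,19,7.123,0.805,Core emerging hotspot
6,Reddit,6,14,4.554,0.699,Potential breakthrough theme
6,Social networking,6,9,3.350,0.627,Exploratory emerging theme
6,Social network analysis,5,3,1.074,0.382,Exploratory emerging theme
6,Vaccine,5,19,7.156,1.018,Potential breakthrough theme
6,Crowdsourcing,4,9,2.570,0.603,Exploratory emerging theme
6,Network analysis,3,8,2.729,0.637,Exploratory emerging theme
6,HPV,2,4,1.603,0.453,Peripheral obsolete theme
6,Recurrent neural networks,2,3,0.789,0.382,Exploratory emerging theme
6,Social media data,2,3,0.746,0.202,Exploratory emerging theme
6,Word embedding,2,2,0.671,0.639,Exploratory emerging theme
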
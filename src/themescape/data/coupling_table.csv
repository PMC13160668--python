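cluster_a,cluster_b,cross_cluster_strength,cross_cluster_strength_text,keyword,source_cluster,contribution
1,4,10.649,10.649,COVID-19,4,3.052
1,4,10.649,10.649,Public health,1,2.104
1,4,10.649,10.649,Twitter,4,2.018
1,4,10.649,10.649,Topic modeling,4,1.549
1,4,10.649,10.649,Coronavirus,4,1.429
4,6,10.404,10.404,Twitter,4,2.724
4,6,10.404,10.404,COVID-19,4,2.540
4,6,10.404,10.404,Deep learning,6,2.271
4,6,10.404,10.404,Sentiment analysis,6,1.650
4,6,10.404,10.404,Topic modeling,4,1.646
3,4,7.989,7.989,COVID-19,4,3.013
3,4,7.989,7.989,Pandemics,3,2.182
3,4,7.989,7.989,Twitter,4,1.973
3,4,7.989,7.989,Attitude,3,1.532
3,4,7.989,7.989,Tweet,4,1.440
2,6,7.216,6.967,Natural language processing,2,2.476
2,6,7.216,6.967,Social media mining,2,2.436
2,6,7.216,6.967,Deep learning,6,1.360
2,6,7.216,6.967,Sentiment analysis,6,1.359
2,6,7.216,6.967,Latent Dirichlet allocation,6,1.288
2,4,6.967,7.216,Natural language processing,2,3.031
2,4,6.967,7.216,COVID-19,4,2.081
2,4,6.967,7.216,Infodemiology,4,1.541
2,4,6.967,7.216,Twitter,4,1.208
2,4,6.967,7.216,Machine learning,2,1.135
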
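network,pollinator_richness,plant_richness,pollinator_weighted_degree,plant_weighted_degree,pollinator_unweighted_degree,plant_unweighted_degree,connectance,nodf,asymmetry
Ireland,148,239,30.66,18.99,10.32,6.39,0.04,30.99,-0.24
Canada,102,12,5.39,45.83,1.64,13.92,0.14,21.01,0.79
Sweden,118,23,3.25,16.65,2.02,10.35,0.09,7.17,0.67
Seychelles,144,38,84.97,321.97,4.03,15.29,0.11,18.89,0.58
Japan,679,93,3.52,25.72,1.78,12.97,0.02,14.70,0.76
UK,79,25,27.63,87.32,3.78,11.96,0.15,18.75,0.52
South Africa,56,9,10.61,66.00,1.84,11.44,0.20,22.35,0.72
Germany Sweden UK,223,199,26.78,30.02,6.09,8.98,0.03,9.01,0.06
Spain,81,32,15.15,38.34,3.94,9.97,0.12,14.69,0.43
USA,44,13,50.57,171.15,3.25,11.00,0.25,24.64,0.54
Argentina,90,14,58.72,377.50,1.82,11.71,0.13,26.94,0.73
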
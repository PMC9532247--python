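network,kind,plant_richness,visitor_richness,plant_weighted_degree,visitor_weighted_degree,plant_unweighted_degree,visitor_unweighted_degree,connectance,nodf,asymmetry
intensively_managed,habitat,134,55,16.75,40.82,3.77,9.18,0.07,30.91,-0.42
coastal_dune,habitat,33,48,20.61,14.17,4.21,2.90,0.09,25.86,0.19
grassland,habitat,131,125,35.76,37.48,6.61,6.93,0.05,27.71,-0.02
woodland_shrub,habitat,91,47,10.54,20.40,2.73,5.28,0.06,23.43,-0.32
agriculture,habitat_subset,56,25,24.43,56.96,4.27,9.56,0.17,46.22,-0.38
urban,habitat_subset,96,42,8.55,19.55,3.02,6.90,0.07,30.38,-0.39
seminatural_grassland,habitat_subset,90,107,30.60,25.74,7.14,6.01,0.07,27.97,0.09
amenity_grassland,habitat_subset,79,70,23.87,26.94,4.34,4.90,0.06,27.90,-0.06
full_habitat_pool,full,238,148,38.39,61.74,6.41,10.31,0.04,30.99,-0.23
may,month,74,72,9.86,10.14,3.49,3.58,0.05,18.12,-0.014
june,month,125,93,15.89,21.35,4.52,6.08,0.05,25.75,-0.15
july,month,127,95,26.60,35.56,4.62,6.18,0.05,29.02,-0.14
august,month,123,86,23.07,33.00,5.04,7.21,0.06,28.18,-0.18
september,month,21,25,9.00,7.56,3.48,2.92,0.14,30.96,0.09
full,full,239,148,18.99,30.66,6.39,10.32,0.04,30.99,-0.24
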
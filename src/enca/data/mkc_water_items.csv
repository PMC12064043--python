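year,selu,code,value
2013,Human footprint,W1_1,21902.0
2013,Agricultural landscape,W1_1,631953.0
2013,Shrubland,W1_1,65950.0
2013,Forest landscape,W1_1,53272.0
2013,Mangrove Landscape,W1_1,245213.0
2013,Wetland,W1_1,1881588.0
2013,Estuary,W1_1,232905.0
2013,Human footprint,W1_2,1560.0
2013,Agricultural landscape,W1_2,91233.0
2013,Shrubland,W1_2,19085.0
2013,Forest landscape,W1_2,52114.0
2013,Mangrove Landscape,W1_2,34641.0
2013,Wetland,W1_2,33945.0
2013,Estuary,W1_2,101.0
2013,Human footprint,W1_4,11924.0
2013,Agricultural landscape,W1_4,52085.0
2013,Shrubland,W1_4,447648.0
2013,Forest landscape,W1_4,125536.0
2013,Mangrove Landscape,W1_4,384629.0
2013,Wetland,W1_4,40479.0
2013,Estuary,W1_4,21999.0
2013,Human footprint,W1_5,4169.0
2013,Agricultural landscape,W1_5,16436.0
2013,Shrubland,W1_5,10240.0
2013,Forest landscape,W1_5,44797.0
2013,Mangrove Landscape,W1_5,63078.0
2013,Wetland,W1_5,11399.0
2013,Estuary,W1_5,3910.0
2013,Human footprint,W2_1,13556.0
2013,Agricultural landscape,W2_1,60836.0
2013,Shrubland,W2_1,123516.0
2013,Forest landscape,W2_1,148094.0
2013,Mangrove Landscape,W2_1,106165.0
2013,Wetland,W2_1,44977.0
2013,Estuary,W2_1,23556.0
2013,Human footprint,W2_2,-52918.0
2013,Agricultural landscape,W2_2,-190448.0
2013,Shrubland,W2_2,-1177985.0
2013,Forest landscape,W2_2,-213204.0
2013,Mangrove Landscape,W2_2,-2155697.0
2013,Wetland,W2_2,-114477.0
2013,Estuary,W2_2,-274299.0
2013,Human footprint,W2_3,54880.0
2013,Agricultural landscape,W2_3,267173.0
2013,Shrubland,W2_3,1264727.0
2013,Forest landscape,W2_3,297375.0
2013,Mangrove Landscape,W2_3,2983773.0
2013,Wetland,W2_3,187558.0
2013,Estuary,W2_3,381044.0
2013,Human footprint,W2_4,3359.0
2013,Agricultural landscape,W2_4,10077.0
2013,Shrubland,W2_4,54257.0
2013,Forest landscape,W2_4,17204.0
2013,Mangrove Landscape,W2_4,1944.0
2013,Wetland,W2_4,11645.0
2013,Estuary,W2_4,41.0
2013,Human footprint,W2_5,5.0
2013,Agricultural landscape,W2_5,23.0
2013,Shrubland,W2_5,26.0
2013,Forest landscape,W2_5,18.0
2013,Mangrove Landscape,W2_5,7.0
2013,Wetland,W2_5,4.0
2013,Estuary,W2_5,0.0
2013,Human footprint,W2_6,7832.0
2013,Agricultural landscape,W2_6,23487.0
2013,Shrubland,W2_6,126536.0
2013,Forest landscape,W2_6,40122.0
2013,Mangrove Landscape,W2_6,4463.0
2013,Wetland,W2_6,27167.0
2013,Estuary,W2_6,93.0
2013,Human footprint,W3_1,13261.0
2013,Agricultural landscape,W3_1,51540.0
2013,Shrubland,W3_1,85930.0
2013,Forest landscape,W3_1,145897.0
2013,Mangrove Landscape,W3_1,47569.0
2013,Wetland,W3_1,47015.0
2013,Estuary,W3_1,18649.0
2013,Human footprint,W3_3,2256.0
2013,Agricultural landscape,W3_3,86021.0
2013,Shrubland,W3_3,124327.0
2013,Forest landscape,W3_3,86368.0
2013,Mangrove Landscape,W3_3,886672.0
2013,Wetland,W3_3,71044.0
2013,Estuary,W3_3,111653.0
2013,Human footprint,W3_4,35872.0
2013,Agricultural landscape,W3_4,107710.0
2013,Shrubland,W3_4,57930.0
2013,Forest landscape,W3_4,18371.0
2013,Mangrove Landscape,W3_4,21405.0
2013,Wetland,W3_4,124263.0
2013,Estuary,W3_4,464.0
2013,Human footprint,W3_8,0.0
2013,Agricultural landscape,W3_8,38.0
2013,Shrubland,W3_8,1181.0
2013,Forest landscape,W3_8,78.0
2013,Mangrove Landscape,W3_8,2223.0
2013,Wetland,W3_8,27.0
2013,Estuary,W3_8,98.0
2013,Human footprint,W14,0.95
2013,Agricultural landscape,W14,0.95
2013,Shrubland,W14,0.95
2013,Forest landscape,W14,0.95
2013,Mangrove Landscape,W14,0.95
2013,Wetland,W14,0.89
2013,Estuary,W14,0.95
2018,Human footprint,W1_1,8690.0
2018,Agricultural landscape,W1_1,460471.0
2018,Shrubland,W1_1,27159.0
2018,Forest landscape,W1_1,19364.0
2018,Mangrove Landscape,W1_1,210324.0
2018,Wetland,W1_1,1746585.0
2018,Estuary,W1_1,46205.0
2018,Human footprint,W1_2,1547.0
2018,Agricultural landscape,W1_2,131401.0
2018,Shrubland,W1_2,21510.0
2018,Forest landscape,W1_2,11479.0
2018,Mangrove Landscape,W1_2,31093.0
2018,Wetland,W1_2,33671.0
2018,Estuary,W1_2,100.0
2018,Human footprint,W1_4,11454.0
2018,Agricultural landscape,W1_4,77640.0
2018,Shrubland,W1_4,465890.0
2018,Forest landscape,W1_4,93036.0
2018,Mangrove Landscape,W1_4,333535.0
2018,Wetland,W1_4,38884.0
2018,Estuary,W1_4,21132.0
2018,Human footprint,W1_5,2363.0
2018,Agricultural landscape,W1_5,14224.0
2018,Shrubland,W1_5,63305.0
2018,Forest landscape,W1_5,20996.0
2018,Mangrove Landscape,W1_5,31830.0
2018,Wetland,W1_5,6618.0
2018,Estuary,W1_5,2235.0
2018,Human footprint,W2_1,7149.0
2018,Agricultural landscape,W2_1,49191.0
2018,Shrubland,W2_1,119260.0
2018,Forest landscape,W2_1,146731.0
2018,Mangrove Landscape,W2_1,103916.0
2018,Wetland,W2_1,43151.0
2018,Estuary,W2_1,21629.0
2018,Human footprint,W2_2,-41746.0
2018,Agricultural landscape,W2_2,-243909.0
2018,Shrubland,W2_2,-2477019.0
2018,Forest landscape,W2_2,-68268.0
2018,Mangrove Landscape,W2_2,-1052898.0
2018,Wetland,W2_2,-88201.0
2018,Estuary,W2_2,-210773.0
2018,Human footprint,W2_3,43550.0
2018,Agricultural landscape,W2_3,320972.0
2018,Shrubland,W2_3,2569369.0
2018,Forest landscape,W2_3,151721.0
2018,Mangrove Landscape,W2_3,1780934.0
2018,Wetland,W2_3,148836.0
2018,Estuary,W2_3,302376.0
2018,Human footprint,W2_4,3910.0
2018,Agricultural landscape,W2_4,20746.0
2018,Shrubland,W2_4,44245.0
2018,Forest landscape,W2_4,12305.0
2018,Mangrove Landscape,W2_4,2965.0
2018,Wetland,W2_4,9902.0
2018,Estuary,W2_4,38.0
2018,Human footprint,W2_5,4.0
2018,Agricultural landscape,W2_5,21.0
2018,Shrubland,W2_5,24.0
2018,Forest landscape,W2_5,14.0
2018,Mangrove Landscape,W2_5,4.0
2018,Wetland,W2_5,3.0
2018,Estuary,W2_5,0.0
2018,Human footprint,W2_6,9118.0
2018,Agricultural landscape,W2_6,48376.0
2018,Shrubland,W2_6,103158.0
2018,Forest landscape,W2_6,28691.0
2018,Mangrove Landscape,W2_6,6842.0
2018,Wetland,W2_6,23099.0
2018,Estuary,W2_6,84.0
2018,Human footprint,W3_1,6589.0
2018,Agricultural landscape,W3_1,41979.0
2018,Shrubland,W3_1,89845.0
2018,Forest landscape,W3_1,144942.0
2018,Mangrove Landscape,W3_1,52164.0
2018,Wetland,W3_1,41758.0
2018,Estuary,W3_1,15748.0
2018,Human footprint,W3_3,2364.0
2018,Agricultural landscape,W3_3,84275.0
2018,Shrubland,W3_3,121765.0
2018,Forest landscape,W3_3,85241.0
2018,Mangrove Landscape,W3_3,779787.0
2018,Wetland,W3_3,62028.0
2018,Estuary,W3_3,97484.0
2018,Human footprint,W3_4,52132.0
2018,Agricultural landscape,W3_4,138291.0
2018,Shrubland,W3_4,58984.0
2018,Forest landscape,W3_4,16404.0
2018,Mangrove Landscape,W3_4,39454.0
2018,Wetland,W3_4,132018.0
2018,Estuary,W3_4,498.0
2018,Human footprint,W3_8,0.0
2018,Agricultural landscape,W3_8,65.0
2018,Shrubland,W3_8,1409.0
2018,Forest landscape,W3_8,3.0
2018,Mangrove Landscape,W3_8,2191.0
2018,Wetland,W3_8,28.0
2018,Estuary,W3_8,120.0
2018,Human footprint,W14,0.95
2018,Agricultural landscape,W14,0.95
2018,Shrubland,W14,0.95
2018,Forest landscape,W14,0.95
2018,Mangrove Landscape,W14,0.95
2018,Wetland,W14,0.87
2018,Estuary,W14,0.95
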
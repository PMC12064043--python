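row,Village,Rice field,Sugar-cane field,Raffia,Crops field,Savannah,Dense dry forest,Sparse dry forest,Dense mangrove,Scattered mangrove,Stunted mangrove,Tan,Shrubland,Barren land,Phragmites,Water bodies
opening,433,4256,4728,959,5817,63937,50031,42800,6816,14482,3047,6530,82737,8391,2284,53514
F_lf1,119,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
F_lf2,0,2529,881,40,8692,1857,0,0,0,0,0,0,0,0,0,7
F_lf3,0,11,228,0,26,0,7899,12855,303,5227,878,521,0,0,0,0
F_lf4,0,0,0,0,0,18129,0,0,0,0,0,0,16898,298,0,0
F_lf5,0,0,0,0,0,165,0,1837,1,292,77,1333,12028,3,0,0
F_lf6,0,0,0,0,0,0,0,0,0,0,0,0,0,721,212,4833
F_lf7,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
total_formation,119,2540,1109,40,8718,20151,7899,14692,304,5519,955,1854,28926,1024,212,4844
C_lf1,0,0,0,0,0,63,0,38,0,0,0,0,17,1,0,0
C_lf2,0,0,0,0,0,2010,774,2778,0,146,0,120,6136,1198,548,296
C_lf3,0,0,0,37,228,0,7805,6255,2189,802,1716,369,8547,0,0,0
C_lf4,0,0,0,0,0,0,2848,16487,0,1844,14,2748,11384,0,0,0
C_lf5,0,0,0,155,16,13807,0,0,0,0,0,0,0,1096,320,342
C_lf6,0,0,0,28,2,377,0,18,1,236,53,198,648,3183,226,798
C_lf7,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
total_consumption,0,0,0,220,246,16257,11427,25576,2190,3028,1783,3435,26732,5478,1094,1436
closing,552,6796,5837,779,14289,67831,46503,31916,4930,16973,2219,4949,84931,3937,1402,56922
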
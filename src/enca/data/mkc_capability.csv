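year,selu,code,value
2013,Human footprint,C10,139219.0
2013,Agricultural landscape,C10,611150.0
2013,Shrubland,C10,1792252.0
2013,Forest landscape,C10,505248.0
2013,Mangrove Landscape,C10,470378.0
2013,Wetland,C10,434790.0
2013,Estuary,C10,197525.0
2013,Human footprint,CIUV,1.0
2013,Agricultural landscape,CIUV,1.0
2013,Shrubland,CIUV,1.0
2013,Forest landscape,CIUV,0.92
2013,Mangrove Landscape,CIUV,0.77
2013,Wetland,CIUV,1.0
2013,Estuary,CIUV,1.0
2013,Human footprint,W6,24456.0
2013,Agricultural landscape,W6,85126.0
2013,Shrubland,W6,266749.0
2013,Forest landscape,W6,203241.0
2013,Mangrove Landscape,W6,53983.0
2013,Wetland,W6,85831.0
2013,Estuary,W6,18782.0
2013,Human footprint,W15,0.72
2013,Agricultural landscape,W15,0.74
2013,Shrubland,W15,0.98
2013,Forest landscape,W15,0.98
2013,Mangrove Landscape,W15,0.87
2013,Wetland,W15,0.7
2013,Estuary,W15,0.97
2013,Human footprint,TEIP_adj,14348.0
2013,Agricultural landscape,TEIP_adj,47757.0
2013,Shrubland,TEIP_adj,255524.0
2013,Forest landscape,TEIP_adj,242975.0
2013,Mangrove Landscape,TEIP_adj,103087.0
2013,Wetland,TEIP_adj,325306.0
2013,Estuary,TEIP_adj,54324.0
2013,Human footprint,EIIUV,0.71
2013,Agricultural landscape,EIIUV,0.97
2013,Shrubland,EIIUV,0.93
2013,Forest landscape,EIIUV,0.81
2013,Mangrove Landscape,EIIUV,0.9
2013,Wetland,EIIUV,0.83
2013,Estuary,EIIUV,0.93
2013,Human footprint,ECU_P,0.81
2013,Agricultural landscape,ECU_P,0.9
2013,Shrubland,ECU_P,0.97
2013,Forest landscape,ECU_P,0.9
2013,Mangrove Landscape,ECU_P,0.84
2013,Wetland,ECU_P,0.84
2013,Estuary,ECU_P,0.97
2013,Human footprint,C_EC,113027.0
2013,Agricultural landscape,C_EC,552392.0
2013,Shrubland,C_EC,1736426.0
2013,Forest landscape,C_EC,455338.0
2013,Mangrove Landscape,C_EC,396642.0
2013,Wetland,C_EC,365739.0
2013,Estuary,C_EC,190670.0
2013,Human footprint,W_EC,19855.0
2013,Agricultural landscape,W_EC,76942.0
2013,Shrubland,W_EC,258441.0
2013,Forest landscape,W_EC,183164.0
2013,Mangrove Landscape,W_EC,45521.0
2013,Wetland,W_EC,72200.0
2013,Estuary,W_EC,18130.0
2013,Human footprint,EI_EC,11649.0
2013,Agricultural landscape,EI_EC,42981.0
2013,Shrubland,EI_EC,247566.0
2013,Forest landscape,EI_EC,218973.0
2013,Mangrove Landscape,EI_EC,86928.0
2013,Wetland,EI_EC,273643.0
2013,Estuary,EI_EC,52439.0
2013,Human footprint,TEC,144532.0
2013,Agricultural landscape,TEC,672315.0
2013,Shrubland,TEC,2242432.0
2013,Forest landscape,TEC,857476.0
2013,Mangrove Landscape,TEC,529091.0
2013,Wetland,TEC,711581.0
2013,Estuary,TEC,261240.0
2013,Total,C_EC,3810235.0
2013,Total,W_EC,674254.0
2013,Total,EI_EC,934179.0
2013,Total,TEC,5418668.0
2018,Human footprint,C10,144252.0
2018,Agricultural landscape,C10,1028158.0
2018,Shrubland,C10,1495989.0
2018,Forest landscape,C10,481878.0
2018,Mangrove Landscape,C10,440956.0
2018,Wetland,C10,466831.0
2018,Estuary,C10,187854.0
2018,Human footprint,CIUV,1.0
2018,Agricultural landscape,CIUV,1.0
2018,Shrubland,CIUV,0.88
2018,Forest landscape,CIUV,0.78
2018,Mangrove Landscape,CIUV,0.74
2018,Wetland,CIUV,1.0
2018,Estuary,CIUV,1.0
2018,Human footprint,W6,19621.0
2018,Agricultural landscape,W6,111121.0
2018,Shrubland,W6,237271.0
2018,Forest landscape,W6,185951.0
2018,Mangrove Landscape,W6,61976.0
2018,Wetland,W6,74761.0
2018,Estuary,W6,15869.0
2018,Human footprint,W15,0.64
2018,Agricultural landscape,W15,0.78
2018,Shrubland,W15,0.98
2018,Forest landscape,W15,0.98
2018,Mangrove Landscape,W15,0.81
2018,Wetland,W15,0.65
2018,Estuary,W15,0.96
2018,Human footprint,TEIP_adj,7000.0
2018,Agricultural landscape,TEIP_adj,49573.0
2018,Shrubland,TEIP_adj,240827.0
2018,Forest landscape,TEIP_adj,171053.0
2018,Mangrove Landscape,TEIP_adj,86126.0
2018,Wetland,TEIP_adj,236614.0
2018,Estuary,TEIP_adj,49862.0
2018,Human footprint,EIIUV,0.71
2018,Agricultural landscape,EIIUV,0.97
2018,Shrubland,EIIUV,0.93
2018,Forest landscape,EIIUV,0.81
2018,Mangrove Landscape,EIIUV,0.9
2018,Wetland,EIIUV,0.83
2018,Estuary,EIIUV,0.93
2018,Human footprint,ECU_P,0.78
2018,Agricultural landscape,ECU_P,0.91
2018,Shrubland,ECU_P,0.93
2018,Forest landscape,ECU_P,0.87
2018,Mangrove Landscape,ECU_P,0.81
2018,Wetland,ECU_P,0.82
2018,Estuary,ECU_P,0.96
2018,Human footprint,C_EC,111871.0
2018,Agricultural landscape,C_EC,931272.0
2018,Shrubland,C_EC,1396558.0
2018,Forest landscape,C_EC,418890.0
2018,Mangrove Landscape,C_EC,359365.0
2018,Wetland,C_EC,382281.0
2018,Estuary,C_EC,181138.0
2018,Human footprint,W_EC,15217.0
2018,Agricultural landscape,W_EC,100651.0
2018,Shrubland,W_EC,221501.0
2018,Forest landscape,W_EC,161645.0
2018,Mangrove Landscape,W_EC,50508.0
2018,Wetland,W_EC,61221.0
2018,Estuary,W_EC,15302.0
2018,Human footprint,EI_EC,5429.0
2018,Agricultural landscape,EI_EC,45111.0
2018,Shrubland,EI_EC,224821.0
2018,Forest landscape,EI_EC,148694.0
2018,Mangrove Landscape,EI_EC,70190.0
2018,Wetland,EI_EC,193760.0
2018,Estuary,EI_EC,48079.0
2018,Human footprint,TEC,132516.0
2018,Agricultural landscape,TEC,1077034.0
2018,Shrubland,TEC,1842880.0
2018,Forest landscape,TEC,729229.0
2018,Mangrove Landscape,TEC,480063.0
2018,Wetland,TEC,637262.0
2018,Estuary,TEC,244520.0
2018,Total,C_EC,3781374.0
2018,Total,W_EC,626045.0
2018,Total,EI_EC,736085.0
2018,Total,TEC,5143504.0
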
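selu,area_open,GBLI_open,HNVI_open,FI_open,NLEP_open,RAWI_open,HNVI_riv_open,frag_riv_open,NREP_open,area_close,GBLI_close,HNVI_close,FI_close,NLEP_close,RAWI_close,HNVI_riv_close,frag_riv_close,NREP_close,EHI
Human footprint,6241,59.91,1.0,0.62,5216,53.38,1.0,1.0,7496,6241,59.37,1.0,0.52,4341,15.01,1.0,1.0,2108,0.94
Agricultural landscape,17408,59.36,1.0,0.55,12788,75.38,1.0,1.0,29524,29596,65.68,1.0,0.47,20556,37.71,1.0,1.0,25115,0.94
Shrubland,121514,69.53,1.0,0.97,184136,15.43,1.0,1.0,42256,129468,68.83,1.0,0.97,194324,9.44,1.0,1.0,27547,0.92
Forest landscape,79706,88.01,1.14,0.98,176876,18.77,1.14,1.0,38396,60649,88.17,1.19,0.97,139212,11.32,1.19,1.0,18377,0.92
Mangrove Landscape,39927,81.75,1.0,0.98,71846,21.69,1.0,1.0,19489,38842,80.35,1.0,0.97,67824,13.18,1.0,1.0,11523,0.96
Wetland,110957,79.1,1.05,0.96,200129,33.46,1.05,1.0,88088,110957,76.62,1.05,0.87,174479,16.53,1.05,1.0,43510,0.93
Estuary,21397,86.23,1.0,1.0,41486,13.8,1.0,1.0,6644,21397,86.52,1.0,1.0,41613,8.98,1.0,1.0,4324,0.94
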
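variable,description,percent_contribution,permutation_importance
bio4,Temperature Seasonality (standard deviation x100),23.3,37.1
bio8,Mean Temperature of Wettest Quarter,18.3,1.6
bio19,Precipitation of Coldest Quarter,17.7,32.8
elev,Elevation,14,5
latitude,Latitude,12,9.6
bio15,Precipitation Seasonality (Coefficient of Variation),3,2.5
bio17,Precipitation of Driest Quarter,2.8,0.5
bio2,Mean Diurnal Range,2.6,0.7
aspect,Aspect,2.2,0.4
bio13,Precipitation of Wettest Month,2.2,4.7
slope,Slope,1,2
bio18,Precipitation of Warmest Quarter,0.9,3.1
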
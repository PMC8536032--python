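land_class,service,available,unit_value_eur_per_ha_month
Forests and Heathland,Food,1,40.0
Forests and Heathland,Materials,1,10.0
Forests and Heathland,Extreme events,1,25.0
Forests and Heathland,Air quality,1,30.0
Forests and Heathland,Water purification,1,35.0
Forests and Heathland,Climate regulation,1,45.0
Forests and Heathland,Hydrological cycle management,1,30.0
Forests and Heathland,BioControl,1,15.0
Forests and Heathland,Pollination,1,20.0
Forests and Heathland,Recreational use,1,50.0
Croplands,Food,1,40.0
Croplands,Materials,1,10.0
Croplands,Extreme events,0,0.0
Croplands,Air quality,1,30.0
Croplands,Water purification,1,35.0
Croplands,Climate regulation,1,45.0
Croplands,Hydrological cycle management,1,30.0
Croplands,BioControl,1,15.0
Croplands,Pollination,1,20.0
Croplands,Recreational use,1,50.0
Coastal ecosystems,Food,1,40.0
Coastal ecosystems,Materials,0,0.0
Coastal ecosystems,Extreme events,1,25.0
Coastal ecosystems,Air quality,1,30.0
Coastal ecosystems,Water purification,0,0.0
Coastal ecosystems,Climate regulation,0,0.0
Coastal ecosystems,Hydrological cycle management,1,30.0
Coastal ecosystems,BioControl,1,15.0
Coastal ecosystems,Pollination,0,0.0
Coastal ecosystems,Recreational use,1,50.0
"Inland waters, wetlands and estuaries",Food,1,40.0
"Inland waters, wetlands and estuaries",Materials,0,0.0
"Inland waters, wetlands and estuaries",Extreme events,1,25.0
"Inland waters, wetlands and estuaries",Air quality,1,30.0
"Inland waters, wetlands and estuaries",Water purification,1,35.0
"Inland waters, wetlands and estuaries",Climate regulation,1,45.0
"Inland waters, wetlands and estuaries",Hydrological cycle management,1,30.0
"Inland waters, wetlands and estuaries",BioControl,1,15.0
"Inland waters, wetlands and estuaries",Pollination,0,0.0
"Inland waters, wetlands and estuaries",Recreational use,1,50.0
Grasslands and Pastures,Food,1,40.0
Grasslands and Pastures,Materials,1,10.0
Grasslands and Pastures,Extreme events,0,0.0
Grasslands and Pastures,Air quality,1,30.0
Grasslands and Pastures,Water purification,1,35.0
Grasslands and Pastures,Climate regulation,1,45.0
Grasslands and Pastures,Hydrological cycle management,1,30.0
Grasslands and Pastures,BioControl,1,15.0
Grasslands and Pastures,Pollination,1,20.0
Grasslands and Pastures,Recreational use,1,50.0
Green Urban Areas,Food,0,0.0
Green Urban Areas,Materials,0,0.0
Green Urban Areas,Extreme events,1,25.0
Green Urban Areas,Air quality,1,30.0
Green Urban Areas,Water purification,1,35.0
Green Urban Areas,Climate regulation,1,45.0
Green Urban Areas,Hydrological cycle management,1,30.0
Green Urban Areas,BioControl,1,15.0
Green Urban Areas,Pollination,1,20.0
Green Urban Areas,Recreational use,1,50.0
SUDS,Food,0,0.0
SUDS,Materials,0,0.0
SUDS,Extreme events,1,25.0
SUDS,Air quality,0,0.0
SUDS,Water purification,1,35.0
SUDS,Climate regulation,1,45.0
SUDS,Hydrological cycle management,1,30.0
SUDS,BioControl,1,15.0
SUDS,Pollination,1,20.0
SUDS,Recreational use,0,0.0
Urban Gardens,Food,1,40.0
Urban Gardens,Materials,1,10.0
Urban Gardens,Extreme events,0,0.0
Urban Gardens,Air quality,1,30.0
Urban Gardens,Water purification,1,35.0
Urban Gardens,Climate regulation,1,45.0
Urban Gardens,Hydrological cycle management,1,30.0
Urban Gardens,BioControl,1,15.0
Urban Gardens,Pollination,1,20.0
Urban Gardens,Recreational use,1,50.0
Green Corridors,Food,0,0.0
Green Corridors,Materials,0,0.0
Green Corridors,Extreme events,1,25.0
Green Corridors,Air quality,1,30.0
Green Corridors,Water purification,1,35.0
Green Corridors,Climate regulation,1,45.0
Green Corridors,Hydrological cycle management,1,30.0
Green Corridors,BioControl,1,15.0
Green Corridors,Pollination,1,20.0
Green Corridors,Recreational use,1,50.0
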
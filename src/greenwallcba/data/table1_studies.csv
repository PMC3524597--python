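study_id,data_year,location,currency,price_kind,price,premium_pct,premium_lo_pct,premium_hi_pct,premium_base,greenery_area,uncertainty_kind,relative_se,price_ref
peck_1999,1999,"Canada, Toronto",CAD,property-price,230000,10.5,6,15,annuity,50,interval,,
hunt_2008,1999,"Canada, Toronto",CAD,property-price,,9,3,15,annuity,50,interval,,peck_1999
gao_asami_tokyo,1999,"Japan, Tokyo",JPY,property-price,602400,1.4,,,property-price,25,reported-se,0.476739,
gao_asami_kitakyushu,2003,"Japan, Kitakyushu",JPY,property-price,73200,2.7,,,property-price,25,reported-se,0.574268,
ichihara_cohen,2000,"US, New York",USD,annual-rent,4000,16.2,,,annuity,50,reported-se,0.493700,
des_rosiers,1999,"Canada, Quebec",CAD,property-price,112000,3.9,,,annuity,50,reported-se,0.499573,
tomalty_recreational,2010,"Canada, Toronto",CAD,property-price,395460,20,,,annuity,50,none,,
tomalty_productive,2010,"Canada, Toronto",CAD,property-price,395460,7,,,annuity,50,none,,
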
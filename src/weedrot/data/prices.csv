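section,key,value
crop_price,winter_wheat,150.0
crop_price,winter_oilseed_rape,330.0
crop_price,spring_barley,135.0
crop_price,spring_beans,200.0
crop_price,spring_oats,130.0
crop_price,fallow,0.0
crop_price,cover_crop,0.0
herbicide_cost,glyphosate,5.0
herbicide_cost,selective,30.0
operation_cost,drilling,60.0
operation_cost,inversion_plough,70.0
operation_cost,min_till,40.0
operation_cost,no_till,10.0
operation_cost,spray_pass,12.0
operation_cost,stale_seedbed_pass,25.0
other_cost,winter_wheat,380.0
other_cost,winter_oilseed_rape,350.0
other_cost,spring_barley,300.0
other_cost,spring_beans,250.0
other_cost,spring_oats,280.0
other_cost,fallow,40.0
other_cost,cover_crop,120.0
meta,price_year,2019.0
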
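county,region,cereal_area_ha,share_LD-LR,share_LD-HR,share_HD-HR
North Yorkshire,north,95000,0.25,0.5,0.25
East Riding of Yorkshire,north,110000,0.25,0.5,0.25
South Yorkshire,north,40000,0.25,0.5,0.25
Nottinghamshire,north,60000,0.25,0.5,0.25
Leicestershire,central,55000,0.12,0.58,0.3
Warwickshire,central,50000,0.12,0.58,0.3
Northamptonshire,central,80000,0.12,0.58,0.3
Oxfordshire,central,70000,0.12,0.58,0.3
Buckinghamshire,central,45000,0.12,0.58,0.3
Bedfordshire,central,40000,0.12,0.58,0.3
Lincolnshire,east,230000,0.08,0.58,0.34
Cambridgeshire,east,120000,0.08,0.58,0.34
Suffolk,east,90000,0.08,0.58,0.34
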
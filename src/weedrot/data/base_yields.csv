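crop,soil,region,yield_t_ha
winter_wheat,heavy,north,8.55
winter_wheat,heavy,central,9.0
winter_wheat,heavy,east,9.45
winter_wheat,medium,north,7.79
winter_wheat,medium,central,8.2
winter_wheat,medium,east,8.61
winter_wheat,light,north,6.65
winter_wheat,light,central,7.0
winter_wheat,light,east,7.35
winter_oilseed_rape,heavy,north,3.325
winter_oilseed_rape,heavy,central,3.5
winter_oilseed_rape,heavy,east,3.675
winter_oilseed_rape,medium,north,3.04
winter_oilseed_rape,medium,central,3.2
winter_oilseed_rape,medium,east,3.36
winter_oilseed_rape,light,north,2.66
winter_oilseed_rape,light,central,2.8
winter_oilseed_rape,light,east,2.94
spring_barley,heavy,north,5.7
spring_barley,heavy,central,6.0
spring_barley,heavy,east,6.3
spring_barley,medium,north,5.32
spring_barley,medium,central,5.6
spring_barley,medium,east,5.88
spring_barley,light,north,4.75
spring_barley,light,central,5.0
spring_barley,light,east,5.25
spring_beans,heavy,north,3.8
spring_beans,heavy,central,4.0
spring_beans,heavy,east,4.2
spring_beans,medium,north,3.61
spring_beans,medium,central,3.8
spring_beans,medium,east,3.99
spring_beans,light,north,3.135
spring_beans,light,central,3.3
spring_beans,light,east,3.465
spring_oats,heavy,north,5.225
spring_oats,heavy,central,5.5
spring_oats,heavy,east,5.775
spring_oats,medium,north,4.94
spring_oats,medium,central,5.2
spring_oats,medium,east,5.46
spring_oats,light,north,4.37
spring_oats,light,central,4.6
spring_oats,light,east,4.83
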
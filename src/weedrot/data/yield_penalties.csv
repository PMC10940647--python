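state,lower,central,upper
absent,0.0,0.0,0.0
low,0.0,0.0,0.0
medium,0.0,0.0,0.0
high,0.075,0.15,0.225
very_high,0.175,0.35,0.525
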
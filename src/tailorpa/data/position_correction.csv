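# Multiplicative count-correction factors by wearing position, belt = 1.0
# reference. The device study applied position corrections but never
# published the factors, so this default table is belt-equivalent (all 1.0);
# supply a calibrated table to use real factors.
position,factor
belt,1.0
pocket,1.0
necklace,1.0
bra,1.0
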
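network,region,x,y,z,radius
DMN,PCC,2,-54,26,6
DAS,IPS R,24,-60,50,6
ECN (L),Left DLPFC,-42,34,20,6
ECN (R),Right DLPFC,44,36,20,6
Motor dorsal (L),Left precentral gyrus hand knob,-28,-26,64,6
Motor dorsal (R),Right precentral gyrus hand knob,34,-24,60,6
Motor ventral (L),Left precentral gyrus ventral,-56,-6,24,6
Motor ventral (R),Right precentral gyrus ventral,60,-2,24,6
Salience (L),Left anterior insula,-32,26,-14,6
Salience (R),Right anterior insula,38,22,-10,6
Visual primary,BA17,8,-78,8,6
Visual secondary,BA18,-22,-90,2,6
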
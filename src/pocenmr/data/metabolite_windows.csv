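Metabolism,Center,From,To
TMSP,0.004,0.106,-0.097
Lactate,1.328,1.354,1.301
GABA3,1.965,1.980,1.950
GABA4,2.299,2.274,2.324
NAA,2.019,2.031,2.006
NAAG,2.053,2.060,2.045
Glu3,2.070,2.077,2.063
Glu4,2.355,2.385,2.325
Gln4,2.438,2.460,2.416
Glx2,3.770,3.810,3.730
Glx3,2.147,2.200,2.094
Suc,2.404,2.411,2.397
Asp3,2.742,2.853,2.631
m-Ins,4.063,4.082,4.044
m-Ins2,3.273,3.298,3.248
m-Ins3,3.584,3.510,3.659
tau,3.427,3.457,3.397
Ala,1.487,1.510,1.465
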
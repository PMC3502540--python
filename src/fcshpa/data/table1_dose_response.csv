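crh_nM,cortisol_nM,cells_per_ml,cells_per_ml_dev,acth_nM,acth_dev_nM
0,0,205164,12889,15.016,0.201
5,0,335938,20522,16.764,0.593
10,0,324219,23935,17.427,0.422
36,0,302084,28168,16.146,0.564
54,0,237500,15630,15.364,0.575
10,50,312500,28125,16.673,0.467
10,100,298438,20625,15.679,0.337
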
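class,model1,model2,model3,model4
all,0.2637,0.2760,0.2513,0.3840
Consolidation,0.3697,0.2006,0.1817,0.3150
Effusion,0.3370,0.3766,0.3460,0.4320
Fibrosis,0.2518,0.2465,0.2202,0.2170
Pneumonia,0.1845,0.1171,0.1375,0.0980
Pneumothorax,0.2899,0.5442,0.4709,0.3910
Nodule,0.1006,0.1505,0.1776,0.1870
Atelectasis,0.3845,0.3333,0.2892,0.4120
Infiltration,0.0000,0.0000,0.0000,0.0000
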
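class,model1,model2,model3,model4
all,0.3460,0.5190,0.5170,0.1800
Consolidation,0.3320,0.2510,0.3070,0.1610
Effusion,0.2880,0.4160,0.4880,0.1560
Fibrosis,0.4190,0.5370,0.5160,0.0816
Pneumonia,0.2600,0.1850,0.3470,0.0952
Pneumothorax,0.3450,0.8290,0.8040,0.2730
Nodule,0.2960,0.4370,0.3340,0.1750
Atelectasis,0.8320,0.5000,0.3430,0.5000
Infiltration,0.0000,1.0000,1.0000,0.0000
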
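class,model1,model2,model3,model4
all,0.2130,0.1880,0.1660,0.2610
Consolidation,0.4170,0.1670,0.1290,0.4170
Effusion,0.4060,0.3440,0.2680,0.4380
Fibrosis,0.1800,0.1600,0.1400,0.1600
Pneumonia,0.1430,0.0857,0.0857,0.1140
Pneumothorax,0.2500,0.4050,0.3330,0.5000
Nodule,0.0606,0.0909,0.1210,0.2120
Atelectasis,0.2500,0.2500,0.2500,0.2500
Infiltration,0.0000,0.0000,0.0000,0.0000
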
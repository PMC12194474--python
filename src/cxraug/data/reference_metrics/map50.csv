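class,model1,model2,model3,model4
all,0.2020,0.2520,0.2800,0.2150
Consolidation,0.3670,0.2730,0.2500,0.2320
Effusion,0.3010,0.3570,0.3230,0.2510
Fibrosis,0.2010,0.2340,0.1960,0.1440
Pneumonia,0.1330,0.0900,0.1240,0.0835
Pneumothorax,0.2220,0.4830,0.4440,0.4470
Nodule,0.1370,0.1450,0.1310,0.1250
Atelectasis,0.2530,0.4350,0.2170,0.4350
Infiltration,0.0025,0.0000,0.5500,0.0000
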
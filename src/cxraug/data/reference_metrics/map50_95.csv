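class,model1,model2,model3,model4
all,0.1110,0.1510,0.1240,0.1240
Consolidation,0.2340,0.1330,0.1240,0.1390
Effusion,0.0555,0.1080,0.0366,0.1030
Fibrosis,0.0475,0.0627,0.0337,0.0684
Pneumonia,0.0651,0.0480,0.0645,0.0621
Pneumothorax,0.0540,0.1650,0.1440,0.2770
Nodule,0.0667,0.0670,0.0623,0.0398
Atelectasis,0.1770,0.3480,0.1520,0.3040
Infiltration,0.0010,0.0000,0.0550,0.0000
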
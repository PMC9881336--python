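participant_id,dataset,sex,group,paretic_side,age,device,le_fugl_meyer,speed_1,speed_2,speed_3,speed_4,has_calibration
S01,1,M,stroke,left,66,AFO,18,0.80,0.90,1.10,1.30,true
S02,1,M,stroke,left,50,none,19,0.90,1.00,1.10,1.20,true
S03,1,M,stroke,left,74,AFO,17,0.30,0.40,0.50,0.70,true
S04,1,F,stroke,left,59,none,31,0.70,0.80,0.90,1.00,true
S05,1,M,stroke,right,61,AFO,14,1.00,1.10,1.20,1.30,true
S06,1,F,stroke,left,66,none,21,0.40,0.50,0.50,0.60,true
S07,1,F,stroke,left,78,none,24,0.70,0.80,0.90,1.00,true
S08,1,M,stroke,right,57,none,15,0.60,0.80,0.90,1.10,true
S09,1,M,stroke,right,75,none,31,0.70,0.90,1.10,1.30,true
S10,1,F,stroke,left,51,AFO,20,0.40,0.50,0.60,0.70,true
S11,1,M,stroke,right,47,none,25,0.80,0.90,1.00,1.10,true
S12,1,M,stroke,right,60,none,25,0.90,1.00,1.20,1.30,true
S13,1,M,stroke,left,52,AFO,20,0.80,1.00,1.20,1.40,true
S14,1,F,stroke,right,62,SPC,25,0.50,0.60,0.80,1.00,true
S15,1,M,stroke,right,72,none,32,0.80,0.90,1.00,1.20,true
S16,1,M,stroke,right,71,"AFO, SPC",19,0.70,0.80,0.90,–,true
S17,1,M,stroke,right,77,none,22,0.70,0.80,0.90,1.10,true
S18,1,F,stroke,left,45,none,23,0.90,1.00,1.10,–,true
S19,1,M,stroke,right,73,none,31,0.70,0.80,1.00,1.30,true
S20,1,M,stroke,left,78,SPC,23,0.50,0.60,0.70,0.90,true
S21,2,M,stroke,left,42,not reported,22,0.77,0.96,1.15,1.24,true
S22,2,F,stroke,right,56,not reported,33,0.46,0.57,0.68,0.81,true
S23,2,F,stroke,right,68,not reported,23,0.21,0.26,0.31,0.56,true
S24,2,M,stroke,right,57,not reported,17,0.48,0.61,0.72,1.00,true
S25,2,M,stroke,left,52,not reported,32,0.82,1.02,1.22,1.35,true
S26,2,M,stroke,left,67,not reported,27,0.26,0.33,0.40,–,true
S27,2,M,stroke,left,54,not reported,31,0.28,0.35,0.42,0.60,true
S28,2,M,stroke,left,60,not reported,33,0.22,0.28,0.34,0.57,true
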
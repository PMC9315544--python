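compound,tissue,mean,sd,available
erlotinib,brain,,,False
erlotinib,lung,0.51,0.2,True
erlotinib,spleen,1.46,0.4,True
erlotinib,kidney,1.69,0.6,True
erlotinib,bone,1.23,0.2,True
erlotinib,tumor,1.42,0.5,True
afatinib,brain,0.08,0.03,True
afatinib,lung,2.54,1.2,True
afatinib,spleen,13.23,2.3,True
afatinib,kidney,6.93,1.8,True
afatinib,bone,4.81,2.0,True
afatinib,tumor,3.60,2.4,True
osimertinib,brain,0.79,0.5,True
osimertinib,lung,7.01,1.6,True
osimertinib,spleen,18.09,7.7,True
osimertinib,kidney,5.61,2.0,True
osimertinib,bone,4.24,0.7,True
osimertinib,tumor,5.60,2.0,True
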
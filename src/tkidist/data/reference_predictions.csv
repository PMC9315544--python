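compound,tissue,predicted
erlotinib,brain,0.13
erlotinib,lung,0.28
erlotinib,spleen,0.17
erlotinib,kidney,0.21
erlotinib,bone,0.14
erlotinib,tumor,0.30
afatinib,brain,2.85
afatinib,lung,6.89
afatinib,spleen,48.72
afatinib,kidney,26.20
afatinib,bone,2.72
afatinib,tumor,15.36
osimertinib,brain,1.52
osimertinib,lung,3.11
osimertinib,spleen,25.33
osimertinib,kidney,10.48
osimertinib,bone,1.48
osimertinib,tumor,2.33
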
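axis,level,condition,n
total,total,ALL,324928
total,total,PMAD,2875
total,total,MDP,3808
total,total,SMI,503
total,total,SUIT,490
total,total,SUB,2894
age,18-19,ALL,32877
age,20-24,ALL,120653
age,25-29,ALL,93254
age,30-34,ALL,50693
age,35-39,ALL,21838
age,40+,ALL,5613
age,18-19,PMAD,284
age,20-24,PMAD,995
age,25-29,PMAD,808
age,30-34,PMAD,500
age,35-39,PMAD,218
age,40+,PMAD,70
age,18-19,MDP,350
age,20-24,MDP,1308
age,25-29,MDP,1151
age,30-34,MDP,656
age,35-39,MDP,279
age,40+,MDP,64
age,18-19,SMI,46
age,20-24,SMI,138
age,25-29,SMI,188
age,30-34,SMI,74
age,35-39,SMI,50
age,40+,SMI,7
age,18-19,SUIT,52
age,20-24,SUIT,171
age,25-29,SUIT,140
age,30-34,SUIT,76
age,35-39,SUIT,34
age,40+,SUIT,17
age,18-19,SUB,156
age,20-24,SUB,887
age,25-29,SUB,979
age,30-34,SUB,599
age,35-39,SUB,213
age,40+,SUB,60
race,White,ALL,136692
race,Black,ALL,144428
race,Other,ALL,39387
race,Unknown,ALL,4421
race,White,PMAD,1564
race,Black,PMAD,1020
race,Other,PMAD,252
race,Unknown,PMAD,39
race,White,MDP,2138
race,Black,MDP,1325
race,Other,MDP,307
race,Unknown,MDP,38
race,White,SMI,219
race,Black,SMI,242
race,Other,SMI,37
race,Unknown,SMI,5
race,White,SUIT,247
race,Black,SUIT,192
race,Other,SUIT,44
race,Unknown,SUIT,7
race,White,SUB,1895
race,Black,SUB,819
race,Other,SUB,159
race,Unknown,SUB,21
ethnicity,NotHispanic,ALL,287633
ethnicity,Hispanic,ALL,30205
ethnicity,Unknown,ALL,7090
ethnicity,NotHispanic,PMAD,2601
ethnicity,Hispanic,PMAD,199
ethnicity,Unknown,PMAD,75
ethnicity,NotHispanic,MDP,3496
ethnicity,Hispanic,MDP,210
ethnicity,Unknown,MDP,102
ethnicity,NotHispanic,SMI,466
ethnicity,Hispanic,SMI,22
ethnicity,Unknown,SMI,15
ethnicity,NotHispanic,SUIT,440
ethnicity,Hispanic,SUIT,35
ethnicity,Unknown,SUIT,15
ethnicity,NotHispanic,SUB,2785
ethnicity,Hispanic,SUB,63
ethnicity,Unknown,SUB,46
insurance,SelfPay,ALL,55438
insurance,Medicaid,ALL,179627
insurance,Private,ALL,74065
insurance,OtherGovt,ALL,9573
insurance,Other,ALL,4899
insurance,Unknown,ALL,663
insurance,SelfPay,PMAD,343
insurance,Medicaid,PMAD,1608
insurance,Private,PMAD,712
insurance,OtherGovt,PMAD,92
insurance,Other,PMAD,104
insurance,Unknown,PMAD,8
insurance,SelfPay,MDP,454
insurance,Medicaid,MDP,2291
insurance,Private,MDP,746
insurance,OtherGovt,MDP,137
insurance,Other,MDP,156
insurance,Unknown,MDP,12
insurance,SelfPay,SMI,58
insurance,Medicaid,SMI,297
insurance,Private,SMI,67
insurance,OtherGovt,SMI,13
insurance,Other,SMI,56
insurance,Unknown,SMI,6
insurance,SelfPay,SUIT,51
insurance,Medicaid,SUIT,300
insurance,Private,SUIT,95
insurance,OtherGovt,SUIT,18
insurance,Other,SUIT,26
insurance,Unknown,SUIT,0
insurance,SelfPay,SUB,656
insurance,Medicaid,SUB,1758
insurance,Private,SUB,355
insurance,OtherGovt,SUB,39
insurance,Other,SUB,80
insurance,Unknown,SUB,3
ruca,Rural,ALL,18107
ruca,Suburban,ALL,45159
ruca,Urban,ALL,196731
ruca,Rural,PMAD,201
ruca,Suburban,PMAD,385
ruca,Urban,PMAD,1715
ruca,Rural,MDP,186
ruca,Suburban,MDP,468
ruca,Urban,MDP,2330
ruca,Rural,SMI,23
ruca,Suburban,SMI,93
ruca,Urban,SMI,300
ruca,Rural,SUIT,18
ruca,Suburban,SUIT,67
ruca,Urban,SUIT,305
ruca,Rural,SUB,217
ruca,Suburban,SUB,494
ruca,Urban,SUB,1893
region,Coastal,ALL,85425
region,Piedmont,ALL,141441
region,Western,ALL,33131
region,Coastal,PMAD,793
region,Piedmont,PMAD,1197
region,Western,PMAD,311
region,Coastal,MDP,1017
region,Piedmont,MDP,1553
region,Western,MDP,414
region,Coastal,SMI,150
region,Piedmont,SMI,220
region,Western,SMI,46
region,Coastal,SUIT,146
region,Piedmont,SUIT,189
region,Western,SUIT,55
region,Coastal,SUB,802
region,Piedmont,SUB,1332
region,Western,SUB,470
ice_income,Q1,ALL,49600
ice_income,Q2,ALL,54824
ice_income,Q3,ALL,69787
ice_income,Q4,ALL,88269
ice_income,Q5,ALL,61630
ice_race,Q1,ALL,116198
ice_race,Q2,ALL,79881
ice_race,Q3,ALL,72302
ice_race,Q4,ALL,41783
ice_race,Q5,ALL,14021
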
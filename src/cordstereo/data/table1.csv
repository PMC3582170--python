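block,measure,unit,Pony,Arabian,Belgium,TB_I,TB_II,mean_printed,se_printed
body,weight,kg,230,300,480,420,450,376,47.6
brain,weight,g,455,490,570,590,555,532,25.5
brain,volume,cm3,425,475,550,560,540,510,25.9
SC,weight,g,207.2,186.3,305.9,267.0,281.6,249.6,22.7
SC,length,cm,142.9,156.2,178.4,175.6,182.8,167.2,7.6
SC,volume,cm3,204.7,180.3,297.1,270.9,283.7,247.3,23.1
CSC,weight,g,87.8,77.3,130.8,116.6,123.4,107.2,10.4
CSC,length,cm,51.4,56.1,65.2,66.0,67.5,61.2,3.2
CSC,volume,cm3,77.4,73.5,111.7,104.1,110.8,95.5,8.3
ratio_CSC_SC,weight,percent,42.4,41.5,42.8,43.7,43.8,42.8,0.4
ratio_CSC_SC,length,percent,36.0,35.9,36.5,37.6,36.9,36.6,0.3
ratio_CSC_SC,volume,percent,37.8,40.8,37.6,38.4,39.0,38.7,0.6
RW,SC,percent,0.090,0.062,0.064,0.064,0.063,0.068,0.005
RW,CSC,percent,0.038,0.026,0.027,0.028,0.027,0.029,0.002
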
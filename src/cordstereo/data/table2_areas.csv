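segment,compartment,unit,mean,se,letters
C1,GS,mm2,132,9.9,c
C1,WM,mm2,115,9.8,b
C1,GM,mm2,16.5,0.7,c
C1,DH,mm2,10.9,0.7,a
C1,VH,mm2,5.6,0.2,cd
C1,CC,1e-3_mm2,58.9,4.3,a
C2,GS,mm2,127,8.5,c
C2,WM,mm2,115,8.1,b
C2,GM,mm2,11.2,0.6,e
C2,DH,mm2,6.6,0.4,c
C2,VH,mm2,4.6,0.2,e
C2,CC,1e-3_mm2,58.1,3.5,a
C3,GS,mm2,120,7.5,c
C3,WM,mm2,111,7.3,b
C3,GM,mm2,9.1,0.3,f
C3,DH,mm2,5.2,0.2,d
C3,VH,mm2,3.9,0.2,e
C3,CC,1e-3_mm2,59.1,5.7,a
C4,GS,mm2,124,8.6,c
C4,WM,mm2,115,8.3,b
C4,GM,mm2,9.0,0.3,f
C4,DH,mm2,5.1,0.2,d
C4,VH,mm2,3.9,0.3,e
C4,CC,1e-3_mm2,53.3,2.6,a
C5,GS,mm2,134,8.7,c
C5,WM,mm2,123,8.2,ab
C5,GM,mm2,10.3,0.5,ef
C5,DH,mm2,5.5,0.3,cd
C5,VH,mm2,4.7,0.3,de
C5,CC,1e-3_mm2,50.9,5.8,ab
C6,GS,mm2,147,10.4,bc
C6,WM,mm2,134,9.8,ab
C6,GM,mm2,12.8,0.6,d
C6,DH,mm2,6.6,0.3,c
C6,VH,mm2,6.2,0.4,c
C6,CC,1e-3_mm2,48.7,6.1,ab
C7,GS,mm2,169,5.0,ab
C7,WM,mm2,147,5.3,a
C7,GM,mm2,22.1,0.4,b
C7,DH,mm2,9.5,0.3,b
C7,VH,mm2,12.6,0.4,b
C7,CC,1e-3_mm2,38.3,4.8,b
C8,GS,mm2,175,8.0,a
C8,WM,mm2,147,7.7,a
C8,GM,mm2,27.8,0.6,a
C8,DH,mm2,11.5,0.5,a
C8,VH,mm2,16.4,0.4,a
C8,CC,1e-3_mm2,37.1,2.8,b
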
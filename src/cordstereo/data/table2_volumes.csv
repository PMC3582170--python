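segment,compartment,unit,mean,se,letters
C1,Arc,cm3,5.7,0.4,c
C1,Total,mm3,3884,387,c
C1,WM,mm3,3402,370,c
C1,GM,mm3,483,30,c
C1,DH,mm3,319,24,b
C1,VH,mm3,164,9,c
C1,CC,1e-3_mm3,1.7,0.12,d
C2,Arc,cm3,14.2,1.5,ab
C2,Total,mm3,10040,1187,a
C2,WM,mm3,9159,1114,a
C2,GM,mm3,880,80,b
C2,DH,mm3,521,49,a
C2,VH,mm3,359,34,b
C2,CC,1e-3_mm3,4.5,0.27,abc
C3,Arc,cm3,17.1,1.8,a
C3,Total,mm3,11693,1679,a
C3,WM,mm3,10813,1587,a
C3,GM,mm3,880,99,b
C3,DH,mm3,502,48,a
C3,VH,mm3,378,54,b
C3,CC,1e-3_mm3,5.6,0.50,a
C4,Arc,cm3,16.9,1.8,a
C4,Total,mm3,11731,1313,a
C4,WM,mm3,10884,1247,a
C4,GM,mm3,847,66,b
C4,DH,mm3,477,36,a
C4,VH,mm3,370,34,b
C4,CC,1e-3_mm3,5.00,0.33,ab
C5,Arc,cm3,15.9,1.8,ab
C5,Total,mm3,11207,1268,a
C5,WM,mm3,10349,1187,a
C5,GM,mm3,858,82,b
C5,DH,mm3,465,53,a
C5,VH,mm3,392,36,b
C5,CC,1e-3_mm3,4.2,0.57,bc
C6,Arc,cm3,14.6,1.3,ab
C6,Total,mm3,10387,972,a
C6,WM,mm3,9480,915,a
C6,GM,mm3,906,59,b
C6,DH,mm3,468,36,a
C6,VH,mm3,439,28,b
C6,CC,1e-3_mm3,3.5,0.58,c
C7,Arc,cm3,11.7,0.9,abc
C7,Total,mm3,8956,670,ab
C7,WM,mm3,7790,621,ab
C7,GM,mm3,1167,61,a
C7,DH,mm3,503,36,a
C7,VH,mm3,664,32,a
C7,CC,1e-3_mm3,2.1,0.33,d
C8,Arc,cm3,8.9,1.0,bc
C8,Total,mm3,6462,5887,bc
C8,WM,mm3,5441,527,bc
C8,GM,mm3,1022,65,ab
C8,DH,mm3,425,41,ab
C8,VH,mm3,597,25,a
C8,CC,1e-3_mm3,1.4,0.13,d
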
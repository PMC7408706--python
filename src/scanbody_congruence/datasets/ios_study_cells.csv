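scanner,sb,n,mean,sd,median,q1,q3
PRIMESCAN,S1,10,25.4,3.5,25.0,23.2,27.0
PRIMESCAN,S2,10,22.6,5.6,20.5,19.2,21.8
PRIMESCAN,S3,10,31.0,3.7,32.0,29.5,33.0
PRIMESCAN,S4,10,28.5,3.0,28.0,27.2,29.8
PRIMESCAN,S5,10,22.2,3.4,21.5,20.0,25.0
PRIMESCAN,S6,10,23.3,4.0,22.0,21.2,23.5
CS3700,S1,10,26.5,4.5,24.5,23.2,29.2
CS3700,S2,10,25.5,3.9,25.5,23.0,26.8
CS3700,S3,10,31.6,2.8,31.5,30.0,33.5
CS3700,S4,10,28.3,2.7,27.0,27.0,28.8
CS3700,S5,10,25.9,4.4,25.0,23.0,27.0
CS3700,S6,10,24.7,4.2,23.0,21.2,28.0
MEDIT_I500,S1,10,27.0,2.3,26.0,25.2,29.0
MEDIT_I500,S2,10,27.0,1.7,26.5,26.0,28.0
MEDIT_I500,S3,10,37.3,2.6,37.0,36.0,37.8
MEDIT_I500,S4,10,34.4,2.6,34.0,33.0,35.0
MEDIT_I500,S5,10,26.1,2.4,25.5,24.2,27.8
MEDIT_I500,S6,10,27.4,2.2,28.0,25.2,29.0
ITERO_5D,S1,10,38.9,19.2,32.5,32.0,34.8
ITERO_5D,S2,10,29.1,1.6,28.0,28.0,30.5
ITERO_5D,S3,10,42.4,2.6,42.5,40.2,43.0
ITERO_5D,S4,10,39.8,1.8,39.5,39.0,40.8
ITERO_5D,S5,10,30.5,2.1,30.5,29.2,32.5
ITERO_5D,S6,10,30.9,2.8,31.0,28.8,32.8
EMERALD_S,S1,10,34.2,2.3,33.0,33.0,36.2
EMERALD_S,S2,10,30.9,2.3,30.5,29.2,31.8
EMERALD_S,S3,10,48.0,2.5,47.5,46.2,49.0
EMERALD_S,S4,10,48.3,2.2,48.5,46.5,49.8
EMERALD_S,S5,10,38.5,2.5,38.5,36.5,39.8
EMERALD_S,S6,10,29.9,2.5,29.5,29.0,30.0
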
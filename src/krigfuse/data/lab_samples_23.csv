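id,x,y,value,instrument,analyte,role,ec,ph
89,84.1,36.6,636,primary,Cu,train,44.0,5.76
89,84.1,36.6,188,primary,Pb,train,44.0,5.76
90,63.4,36.4,4437,primary,Cu,train,17.8,5.69
90,63.4,36.4,811,primary,Pb,train,17.8,5.69
91,135.8,127.4,1080,primary,Cu,train,26.3,5.04
91,135.8,127.4,223,primary,Pb,train,26.3,5.04
92,30.1,163.2,17,primary,Cu,train,27.1,4.72
92,30.1,163.2,26,primary,Pb,train,27.1,4.72
93,81.5,13.8,57,primary,Cu,train,32.4,4.56
93,81.5,13.8,81,primary,Pb,train,32.4,4.56
94,238.8,64.2,1338,primary,Cu,train,36.4,5.01
94,238.8,64.2,402,primary,Pb,train,36.4,5.01
95,55.5,165.7,33,primary,Cu,train,51.3,4.8
95,55.5,165.7,59,primary,Pb,train,51.3,4.8
96,218.2,9.1,29,primary,Cu,train,30.1,5.57
96,218.2,9.1,46,primary,Pb,train,30.1,5.57
97,152.3,142.4,344,primary,Cu,train,27.6,4.68
97,152.3,142.4,94,primary,Pb,train,27.6,4.68
98,240.6,131.4,1535,primary,Cu,train,13.7,5.32
98,240.6,131.4,872,primary,Pb,train,13.7,5.32
99,134.2,163.9,4041,primary,Cu,train,22.4,4.93
99,134.2,163.9,1924,primary,Pb,train,22.4,4.93
100,69.8,165.5,48,primary,Cu,train,48.3,5.09
100,69.8,165.5,29,primary,Pb,train,48.3,5.09
V1,14.6,118.6,1517,primary,Cu,validation,29.7,4.95
V1,14.6,118.6,602,primary,Pb,validation,29.7,4.95
V2,25.7,57.5,2364,primary,Cu,validation,26.7,5.01
V2,25.7,57.5,562,primary,Pb,validation,26.7,5.01
V3,126.2,35.6,1176,primary,Cu,validation,35.4,5.2
V3,126.2,35.6,262,primary,Pb,validation,35.4,5.2
V4,109.1,106.8,3814,primary,Cu,validation,30.3,4.95
V4,109.1,106.8,1545,primary,Pb,validation,30.3,4.95
V5,12.9,4.7,334,primary,Cu,validation,38.2,4.89
V5,12.9,4.7,114,primary,Pb,validation,38.2,4.89
V6,249.1,13.2,48,primary,Cu,validation,59.6,4.88
V6,249.1,13.2,29,primary,Pb,validation,59.6,4.88
V7,59.5,155.7,2454,primary,Cu,validation,65.0,4.41
V7,59.5,155.7,695,primary,Pb,validation,65.0,4.41
V8,173.7,107.3,1368,primary,Cu,validation,31.7,5.1
V8,173.7,107.3,536,primary,Pb,validation,31.7,5.1
V9,111.5,112.9,69,primary,Cu,validation,14.5,5.47
V9,111.5,112.9,32,primary,Pb,validation,14.5,5.47
V10,58.4,121.9,589,primary,Cu,validation,37.1,5.21
V10,58.4,121.9,132,primary,Pb,validation,37.1,5.21
V11,156.4,118.6,567,primary,Cu,validation,50.9,5.38
V11,156.4,118.6,187,primary,Pb,validation,50.9,5.38
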
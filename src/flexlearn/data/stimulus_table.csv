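dim,value,CS1,CS2,CS3,CS4,CS5,CS6,CS7,CS8,CS9,CS10
1,1.0,1.0,2.0,2.0,2.0,1.0,1.0,2.0,1.0,1.0,2.0
2,0.0,0,1,1,1,0,0,1,0,0,0
3,1.0,0,0,1,0,0,0,0,0,0,0
4,-1.0,0,0,0,1,0,0,0,0,0,0
5,2.0,0,0,0,0,1,0,0,0,0,0
6,1.0,0,0,0,0,0,1,0,0,0,0
7,-1.0,0,0,0,0,0,0,1,0,0,0
8,2.0,0,0,0,0,0,0,0,1,0,0
9,1.0,0,0,0,0,0,0,0,0,1,0
10,-1.0,0,0,0,0,0,0,0,0,0,1
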
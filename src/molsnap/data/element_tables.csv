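symbol,covalent_radius_A,vdw_radius_A,cpk_r,cpk_g,cpk_b
H,0.37,1.20,255,255,255
He,0.32,1.40,217,255,255
Li,1.34,1.82,204,128,255
Be,0.90,1.53,194,255,0
B,0.82,1.92,255,181,181
C,0.77,1.70,144,144,144
N,0.75,1.55,48,80,248
O,0.73,1.52,255,13,13
F,0.71,1.47,144,224,80
Ne,0.69,1.54,179,227,245
Na,1.54,2.27,171,92,242
Mg,1.30,1.73,138,255,0
Al,1.18,1.84,191,166,166
Si,1.11,2.10,240,200,160
P,1.06,1.80,255,128,0
S,1.02,1.80,255,255,48
Cl,0.99,1.75,31,240,31
Ar,0.97,1.88,128,209,227
K,1.96,2.75,143,64,212
Ca,1.74,2.31,61,255,0
Fe,1.25,2.00,224,102,51
Cu,1.38,1.40,200,128,51
Zn,1.31,1.39,125,128,176
As,1.19,1.85,189,128,227
Se,1.16,1.90,255,161,0
Br,1.14,1.85,166,41,41
Sn,1.41,2.17,102,128,128
I,1.33,1.98,148,0,148
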
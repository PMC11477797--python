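# Carbon-scaled atomic property weights for descriptor computation.
# m: atomic mass / mass(C); p: static polarizability / pol(C=1.76 A^3);
# e: Sanderson electronegativity / EN(C=2.746); v: van der Waals volume / vol(C);
# i: first ionization potential / IP(C=11.26 eV).
# Values follow the standard molecular-descriptor handbook tables; edit to
# recalibrate against a reference descriptor engine.
element,m,p,e,v,i
H,0.084,0.379,0.944,0.299,1.208
B,0.900,1.722,0.703,0.702,0.737
C,1.000,1.000,1.000,1.000,1.000
N,1.166,0.625,1.163,0.695,1.291
O,1.332,0.456,1.331,0.512,1.209
F,1.582,0.316,1.457,0.410,1.547
Si,2.339,3.057,0.779,1.580,0.724
P,2.579,2.063,0.916,1.181,0.931
S,2.670,1.648,1.077,1.380,0.920
Cl,2.952,1.239,1.265,1.038,1.152
Br,6.653,1.733,1.172,1.259,1.049
I,10.566,3.040,1.012,1.748,0.928
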
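symbol,covalent_radius,r,g,b,valence_electrons,mass,p_block
H,0.31,255,255,255,1,1.008,0
He,0.28,217,255,255,2,4.003,0
Li,1.28,204,128,255,1,6.941,0
Be,0.96,194,255,0,2,9.012,0
B,0.84,255,181,181,3,10.812,1
C,0.76,144,144,144,4,12.011,1
N,0.71,48,80,248,5,14.007,1
O,0.66,255,13,13,6,15.999,1
F,0.57,144,224,80,7,18.998,1
Ne,0.58,179,227,245,8,20.18,1
Na,1.66,171,92,242,1,22.99,0
Mg,1.41,138,255,0,2,24.305,0
Al,1.21,191,166,166,3,26.982,1
Si,1.11,240,200,160,4,28.086,1
P,1.07,255,128,0,5,30.974,1
S,1.05,255,255,48,6,32.067,1
Cl,1.02,31,240,31,7,35.453,1
Ar,1.06,128,209,227,8,39.948,1
K,2.03,143,64,212,1,39.098,0
Ca,1.76,61,255,0,2,40.078,0
Sc,1.70,230,230,230,0,44.956,0
Ti,1.60,191,194,199,0,47.867,0
V,1.52,166,166,171,0,50.944,0
Cr,1.39,138,153,199,0,51.996,0
Mn,1.39,156,122,199,0,54.938,0
Fe,1.32,224,102,51,0,55.845,0
Co,1.26,240,144,160,0,58.933,0
Ni,1.24,80,208,80,0,58.693,0
Cu,1.32,200,128,51,0,63.546,0
Zn,1.22,125,128,176,0,65.39,0
Ga,1.22,194,143,143,3,69.723,1
Ge,1.20,102,143,143,4,72.61,1
As,1.19,189,128,227,5,74.922,1
Se,1.20,255,161,0,6,78.96,1
Br,1.20,166,41,41,7,79.904,1
Kr,1.16,92,184,209,8,83.8,1
Rb,2.20,112,46,176,1,85.468,0
Sr,1.95,0,255,0,2,87.62,0
Y,1.90,148,255,255,0,88.906,0
Zr,1.75,148,224,224,0,91.224,0
Nb,1.64,115,194,201,0,92.906,0
Mo,1.54,84,181,181,0,95.94,0
Tc,1.47,59,158,158,0,98.0,0
Ru,1.46,36,143,143,0,101.07,0
Rh,1.42,10,125,140,0,102.906,0
Pd,1.39,0,105,133,0,106.42,0
Ag,1.45,192,192,192,0,107.868,0
Cd,1.44,255,217,143,0,112.412,0
In,1.42,166,117,115,3,114.818,1
Sn,1.39,102,128,128,4,118.711,1
Sb,1.39,158,99,181,5,121.76,1
Te,1.38,212,122,0,6,127.6,1
I,1.39,148,0,148,7,126.904,1
Xe,1.40,66,158,176,8,131.29,1
Cs,2.44,87,23,143,1,132.905,0
Ba,2.15,0,201,0,2,137.328,0
La,2.07,112,212,255,0,138.906,0
Ce,2.04,255,255,199,0,140.116,0
Pr,2.03,217,255,199,0,140.908,0
Nd,2.01,199,255,199,0,144.24,0
Pm,1.99,163,255,199,0,145.0,0
Sm,1.98,143,255,199,0,150.36,0
Eu,1.98,97,255,199,0,151.964,0
Gd,1.96,69,255,199,0,157.25,0
Tb,1.94,48,255,199,0,158.925,0
Dy,1.92,31,255,199,0,162.5,0
Ho,1.92,0,255,156,0,164.93,0
Er,1.89,0,230,117,0,167.26,0
Tm,1.90,0,212,82,0,168.934,0
Yb,1.87,0,191,56,0,173.04,0
Lu,1.87,0,171,36,0,174.967,0
Hf,1.75,77,194,255,0,178.49,0
Ta,1.70,77,166,255,0,180.948,0
W,1.62,33,148,214,0,183.84,0
Re,1.51,38,125,171,0,186.207,0
Os,1.44,38,102,150,0,190.23,0
Ir,1.41,23,84,135,0,192.217,0
Pt,1.36,208,208,224,0,195.078,0
Au,1.36,255,209,35,0,196.967,0
Hg,1.32,184,184,208,0,200.59,0
Tl,1.45,166,84,77,3,204.383,1
Pb,1.46,87,89,97,4,207.2,1
Bi,1.48,158,79,181,5,208.98,1
Po,1.40,171,92,0,6,209.0,1
At,1.50,117,79,69,7,210.0,1
Rn,1.50,66,130,150,8,222.0,1
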
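protein,section,sub1,sub2,sub3,sub4
EGF,a,-0.26,2.75,3.01,3.42
PDGF-A,a,-0.11,2.71,2.67,3.16
PDGF-B,a,-0.16,2.80,2.65,3.17
TCN2,a,-0.21,2.04,1.76,2.26
STIP1,a,-0.41,1.50,1.56,2.10
SRC,a,-0.30,1.13,0.71,0.46
GLO1,a,0.83,0.76,0.63,0.48
MMP7,b,1.68,0.54,1.70,1.52
CCL24,b,3.52,0.86,3.61,4.29
TNF,b,1.52,-0.35,1.18,1.21
MPO,b,1.51,0.18,1.56,1.50
CCL4,b,3.15,-0.52,2.71,3.24
CD5,b,1.25,-0.02,1.11,1.01
TR-AP,b,1.37,-0.48,1.69,1.85
AZU1,b,2.60,0.14,2.60,2.40
GZMA,b,1.09,0.19,0.76,0.59
IL-1ra,b,4.12,0.71,3.68,3.48
LOX-1,b,1.94,0.07,2.09,1.95
CTSS,b,1.79,0.73,1.20,0.96
TNF-R2,b,0.47,-0.05,0.58,0.64
CCL3,b,1.85,-1.28,2.28,2.70
IL16,b,0.58,0.22,0.68,0.54
GNLY,b,1.83,0.74,1.72,2.47
CXCL16,b,0.98,0.29,0.88,1.04
CHI3L1,b,0.95,0.34,0.78,0.46
KYNU,b,0.36,0.31,0.64,0.37
CCL17,b,0.90,0.52,0.57,1.40
MSR1,b,0.44,0.17,0.34,0.34
STC1,b,3.44,3.18,1.21,0.55
TIMP1,c,0.14,-0.22,-0.81,-0.65
CCL17,c,-0.50,-0.88,-0.83,-1.40
SAA4,c,-0.23,-0.28,-0.24,-0.30
CCL19,c,-0.45,-0.67,-0.70,-0.75
PAI,c,0.14,-0.04,-0.62,-0.33
CXCL11,c,-1.04,-0.57,-0.90,-1.07
SNAP29,c,-2.00,-2.27,-1.96,-2.03
SPINK1,c,-0.99,-1.20,-0.95,-1.21
TNFRSF13B,c,-0.54,-0.53,-0.42,-0.64
ADM,c,1.13,1.67,-2.11,-2.90
OPG,d,5.47,5.44,1.53,0.57
ANGPTL4,d,6.46,6.28,1.17,1.07
TNFRSF12A,d,2.99,2.83,0.68,0.51
SPON1,d,3.04,3.22,2.25,1.91
Gal-1,d,3.58,3.22,1.42,1.30
NRP2,d,1.82,1.22,0.77,0.11
CSTB,d,1.07,0.79,0.64,0.35
FAP,d,0.84,0.62,0.41,0.25
DKK3,d,2.34,2.19,1.09,0.84
A2-MRAP,d,1.52,1.20,1.25,0.82
RGMB,d,2.72,2.87,1.20,0.82
MFGE8,d,5.38,5.24,1.44,1.05
IL6,d,10.60,8.19,2.23,0.25
THY1,d,5.09,4.72,1.23,0.70
N2DL-2,d,1.29,1.78,0.61,0.24
IDUA,d,2.86,3.04,1.20,0.86
AXL,d,2.04,1.92,0.55,0.39
CTSF,d,0.75,0.99,0.43,0.06
FAS,d,2.19,1.96,0.82,0.49
IL15,d,2.42,1.69,0.56,0.51
SKR3,d,1.04,1.05,0.66,0.30
Upa,d,6.98,6.85,1.85,2.09
LTBR,d,1.86,1.79,0.67,0.27
GAS6,d,2.27,2.02,1.90,1.48
GDNF,d,3.09,3.60,1.65,0.99
FS,d,4.41,4.73,1.53,1.50
SCF,d,1.13,1.15,0.47,0.27
CKAP4,d,4.81,4.71,3.51,2.78
PDGF-RA,d,1.51,1.68,1.29,1.05
Gal-3,d,1.32,1.07,0.74,0.55
PVR,d,0.85,0.52,0.45,0.16
ROBO1,d,1.09,0.97,0.65,0.42
PD-L1,d,0.95,0.85,0.56,0.35
C1QTNF1,d,1.67,1.48,1.22,-0.10
NMNAT1,d,1.88,1.31,1.70,0.91
ADA,d,0.90,0.29,0.46,0.34
JAM-B,d,0.62,0.41,0.43,0.15
FSTL3,d,0.77,0.78,0.65,0.57
BLVRB,d,1.21,0.81,1.01,0.81
EZR,d,0.75,0.59,0.60,0.15
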
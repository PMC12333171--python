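protein,sections,med,pbmc,rmsc,coc,d3
EGF,a,5.08,5.33,2.33,2.06,1.65
PDGF-A,a,5.95,6.05,3.24,3.28,2.78
PDGF-B,a,6.17,6.33,3.37,3.52,3.00
TCN2,a,8.76,8.97,6.72,7.01,6.51
STIP1,a,5.17,5.58,3.67,3.61,3.07
SRC,a,5.29,5.60,4.17,4.59,4.83
GLO1,a,3.03,2.20,2.27,2.40,2.55
MMP7,b,5.20,6.35,5.18,6.88,5.37
CCL24,b,5.54,8.20,5.46,9.06,4.78
TNF,b,0.55,2.43,0.90,2.08,0.86
MPO,b,2.52,3.84,2.46,4.02,2.52
CCL4,b,1.10,4.77,1.54,4.25,1.02
CD5,b,1.04,2.32,1.19,2.29,1.28
TR-AP,b,4.02,5.87,3.70,5.39,3.54
AZU1,b,2.50,4.96,2.50,5.10,2.70
GZMA,b,1.03,1.93,1.36,2.12,1.54
IL-1ra,b,0.08,3.48,0.52,4.20,0.72
LOX-1,b,1.01,2.88,0.86,2.95,0.99
CTSS,b,1.51,2.57,2.10,3.30,2.34
TNF-R2,b,5.08,5.60,4.97,5.55,4.91
CCL3,b,3.28,6.42,2.86,5.13,2.43
IL16,b,0.91,1.27,0.81,1.49,0.95
GNLY,b,3.40,4.49,3.51,5.23,2.76
CXCL16,b,4.60,5.29,4.70,5.59,4.55
CHI3L1,b,5.49,6.10,5.66,6.44,5.98
KYNU,b,1.45,1.50,1.16,1.81,1.43
CCL17,"b,c",4.92,5.30,5.24,5.82,4.42
MSR1,b,1.12,1.39,1.22,1.56,1.22
STC1,b,0.61,0.86,2.83,4.04,3.49
TIMP1,c,9.87,10.23,10.82,10.66,10.01
SAA4,c,8.43,8.47,8.44,8.49,8.20
CCL19,c,2.47,2.69,2.72,2.76,2.02
PAI,c,8.66,8.84,9.43,9.14,8.81
CXCL11,c,2.16,1.69,2.02,2.19,1.12
SNAP29,c,8.16,8.43,8.13,8.19,6.17
SPINK1,c,2.71,2.92,2.67,2.94,1.72
TNFRSF13B,c,3.54,3.54,3.43,3.64,3.01
ADM,c,1.55,1.01,4.79,5.58,2.68
OPG,d,2.66,2.69,6.60,7.56,8.13
ANGPTL4,d,3.40,3.58,8.69,8.78,9.86
TNFRSF12A,d,0.51,0.66,2.81,2.99,3.49
SPON1,d,1.94,1.76,2.73,3.07,4.98
Gal-1,d,1.75,2.12,3.91,4.04,5.34
NRP2,d,1.74,2.34,2.79,3.45,3.56
CSTB,d,5.41,5.69,5.84,6.13,6.48
FAP,d,3.82,4.03,4.24,4.40,4.66
DKK3,d,4.54,4.70,5.80,6.05,6.89
A2-MRAP,d,2.92,3.24,3.20,3.62,4.44
RGMB,d,1.16,1.01,2.67,3.06,3.87
MFGE8,d,3.42,3.56,7.36,7.74,8.80
IL6,d,1.29,3.70,9.65,11.63,11.89
THY1,d,2.75,3.12,6.61,7.14,7.84
N2DL-2,d,1.21,0.72,1.89,2.25,2.49
IDUA,d,-0.22,-0.41,1.43,1.77,2.64
AXL,d,8.52,8.64,10.01,10.16,10.56
CTSF,d,1.29,1.05,1.61,1.98,2.04
FAS,d,5.80,6.03,7.17,7.50,7.99
IL15,d,1.37,2.10,3.23,3.28,3.79
SKR3,d,1.07,1.07,1.46,1.82,2.11
Upa,d,4.29,4.42,9.42,9.17,11.27
LTBR,d,2.88,2.95,4.07,4.47,4.74
GAS6,d,8.72,8.98,9.09,9.51,10.99
GDNF,d,1.86,1.35,3.30,3.96,4.95
FS,d,2.83,2.51,5.72,5.75,7.25
SCF,d,2.41,2.39,3.07,3.27,3.54
CKAP4,d,2.77,2.87,4.07,4.80,7.58
PDGF-RA,d,1.36,1.19,1.58,1.82,2.87
Gal-3,d,4.24,4.49,4.82,5.01,5.56
PVR,d,1.75,2.07,2.14,2.43,2.59
ROBO1,d,2.66,2.78,3.10,3.33,3.76
PD-L1,d,1.41,1.51,1.80,2.01,2.36
C1QTNF1,d,8.18,8.37,8.63,9.95,9.85
NMNAT1,d,1.69,2.26,1.87,2.66,3.57
ADA,d,2.51,3.12,2.95,3.07,3.41
JAM-B,d,0.80,1.01,0.99,1.27,1.42
FSTL3,d,1.90,1.89,2.02,2.10,2.67
BLVRB,d,2.68,3.07,2.88,3.07,3.88
EZR,d,0.52,0.69,0.67,1.13,1.27
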
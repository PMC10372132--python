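camera,collimator,hole_diameter_mm,septum_mm,length_mm,energy_class
GE Infinia,LEHR,1.50,0.20,35.00,le
GE Infinia,ELEGP,2.50,0.40,40.00,lme
GE Infinia,MEGP,3.00,1.05,58.00,me
Millennium VG,LEHR,1.50,0.20,35.00,le
Millennium VG,LEGP,1.90,0.20,35.00,le
Millennium VG,MEGP,3.00,1.05,58.00,me
Millennium MG,LEHR,1.80,0.18,41.00,le
Millennium MG,LEGP,2.50,0.25,43.00,le
Millennium MG,MEGP,3.00,1.20,42.00,me
Philips Brightview,CHR,2.03,0.152,48.00,le
Philips Brightview,MEGP,3.40,0.86,58.40,me
SIEMENS E.CAM,LEHR,1.11,0.16,24.05,le
SIEMENS E.CAM,MELP,2.94,1.14,40.64,me
Symbia,LEHR,1.11,0.16,24.05,le
Symbia,MELP,2.94,1.14,40.64,me
Picker AXIS/IRIX,LEHR,1.22,0.20,27.00,le
Picker AXIS/IRIX,LEGP,1.40,0.25,25.40,le
Picker AXIS/IRIX,MEGP,3.40,0.86,58.40,me
GE Discovery,LEHR,1.50,0.20,35.00,le
GE Discovery,ELEGP,2.50,0.40,40.00,lme
GE Discovery,MEGP,3.00,1.05,58.00,me
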
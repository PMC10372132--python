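preset,crystal_in,crystal_mm,intrinsic_res_mm,energy_res_pct,le_camera,le_collimator,me_camera,me_collimator
standard,3/8,9.5,3.8,9.8,GE Discovery,LEHR,GE Discovery,MEGP
GE Infinia 3/8,3/8,9.5,3.8,9.8,GE Infinia,LEHR,GE Infinia,MEGP
Millennium MG 3/8,3/8,9.5,3.7,9.7,Millennium MG,LEHR,Millennium MG,MEGP
NMCT 3/8,3/8,9.5,3.7,9.5,GE Discovery,LEHR,GE Discovery,MEGP
NMCT 5/8,5/8,15.9,4.5,9.5,GE Discovery,LEHR,GE Discovery,MEGP
Philips Brightview 3/8,3/8,9.5,3.3,9.6,Philips Brightview,CHR,Philips Brightview,MEGP
SIEMENS E.CAM 3/8,3/8,9.5,3.8,9.9,SIEMENS E.CAM,LEHR,SIEMENS E.CAM,MELP
SIEMENS E.CAM 5/8,5/8,15.9,4.5,9.9,SIEMENS E.CAM,LEHR,SIEMENS E.CAM,MELP
Picker AXIS/IRIX 3/8,3/8,9.5,3.3,9.5,Picker AXIS/IRIX,LEHR,Picker AXIS/IRIX,MEGP
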
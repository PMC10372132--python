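# Mass attenuation coefficients mu/rho (cm^2/g), coarse grid from standard
# photon cross-section compilations; log-log interpolated at query time.
# Densities used downstream: Pb 11.34, NaI(Tl) 3.667, PMMA 1.19 g/cm^3.
energy_kev,pb,nai,pmma
100,5.549,1.577,0.1641
150,2.014,0.5863,0.1456
159,1.910,0.5450,0.1437
200,0.9985,0.3021,0.1328
250,0.5870,0.2070,0.1229
300,0.4031,0.1614,0.1152
350,0.3032,0.1362,0.1086
400,0.2323,0.1183,0.1031
450,0.1927,0.1055,0.0983
500,0.1613,0.0955,0.0941
550,0.1407,0.0885,0.0904
600,0.1248,0.0826,0.0871
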
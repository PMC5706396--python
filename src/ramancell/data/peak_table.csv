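component,center_cm1,fwhm_cm1,rel_amplitude,profile
dna_rna,785,12,1.00,lorentzian
dna_rna,1098,12,0.35,lorentzian
dna_rna,1334,12,0.65,lorentzian
dna_rna,1371,12,0.45,lorentzian
dna_rna,1484,12,0.75,lorentzian
dna_rna,1575,12,0.85,lorentzian
cyt_c,748,10,1.20,lorentzian
cyt_c,1127,10,0.90,lorentzian
cyt_c,1585,10,1.10,lorentzian
lipid,1073,14,0.30,lorentzian
lipid,1305,14,0.80,lorentzian
lipid,1440,16,1.00,lorentzian
lipid,1738,12,0.25,lorentzian
lipid,2850,20,1.50,lorentzian
protein,1003,8,0.70,lorentzian
protein,1244,16,0.55,lorentzian
protein,1450,16,0.80,lorentzian
protein,1608,10,0.20,lorentzian
protein,1665,30,1.00,lorentzian
protein,2930,26,1.10,lorentzian
substrate_background,900,1400,0.25,gaussian
substrate_background,2950,500,0.08,gaussian
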
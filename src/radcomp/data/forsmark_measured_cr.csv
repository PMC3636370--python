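isotope,group,gm_m3_per_kgC,ci95_lower,ci95_upper,status
Ni-59,phytoplankton,3.70e1,,,measured
Cs-135,phytoplankton,3.00e0,3.30e-1,3.30e0,measured
Th-230,phytoplankton,2.70e3,2.00e3,3.64e3,measured
Ni-59,zooplankton,3.10e1,,,measured
Cs-135,zooplankton,2.56e1,6.98e-1,2.30e2,measured
Th-230,zooplankton,3.20e1,4.65e0,4.65e3,measured
Ni-59,fish,2.10e-1,1.90e-1,2.50e-1,measured
Cs-135,fish,2.20e0,8.30e-1,5.80e0,measured
Th-230,fish,1.30e0,2.50e-1,6.90e0,measured
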
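beam,let_kev_um,probe,mu,mu_err
H230,0.41,grain_4um,1.02,0.03
H230,0.41,grain_38um,0.97,0.03
H230,0.41,single_crystal,0.77,0.06
H160,0.54,grain_4um,1.01,0.02
H160,0.54,grain_38um,0.96,0.03
H160,0.54,single_crystal,0.76,0.07
He150,2.25,grain_4um,0.95,0.02
He150,2.25,grain_38um,0.90,0.02
He150,2.25,single_crystal,0.71,0.07
C400,11.22,grain_4um,0.75,0.04
C400,11.22,grain_38um,0.71,0.03
C400,11.22,single_crystal,0.56,0.08
C290,13.50,grain_4um,0.73,0.03
C290,13.50,grain_38um,0.69,0.02
C290,13.50,single_crystal,0.55,0.08
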
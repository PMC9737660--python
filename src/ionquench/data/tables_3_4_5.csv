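beam,row_kind,depth_mm,species,fluence_pct,let_kev_um
H230,entrance,0.10,H-1,99.999,0.381
H230,entrance,0.10,He-4,3.6e-3,83.62
H230,entrance,0.10,Li-7,4.5e-5,502.442
H230,plateau,170.42,H-1,99.994,0.567
H230,plateau,170.42,He-4,4.2e-3,82.92
H230,plateau,170.42,Li-7,4.1e-5,490.233
H230,peak,317.74,H-1,99.994,3.01
H230,peak,317.74,He-4,4.1e-3,122.07
H230,peak,317.74,Li-7,3.3e-6,519.452
H230,falloff,329.4,H-1,99.981,6.987
H230,falloff,329.4,He-4,12.8e-3,115.18
H230,falloff,329.4,Li-7,2.3e-4,575.503
H160,entrance,0.10,H-1,99.995,0.496
H160,entrance,0.10,He-4,3.4e-3,84.60
H160,entrance,0.10,Li-7,3.9e-5,536.542
H160,plateau,110.8,H-1,99.995,0.842
H160,plateau,110.8,He-4,3.8e-3,87.27
H160,plateau,110.8,Li-7,4.6e-5,528.111
H160,peak,164.81,H-1,99.996,3.820
H160,peak,164.81,He-4,2.7e-3,127.22
H160,peak,164.81,Li-7,2.7e-5,555.512
H160,falloff,168.8,H-1,99.997,7.93
H160,falloff,168.8,He-4,1.7e-3,104.29
H160,falloff,168.8,Li-7,7.7e-5,583.401
He150,entrance,0.10,He-4,99.636,2.077
He150,entrance,0.10,H-1,0.360,3.94
He150,entrance,0.10,Li-7,4.00e-4,423.292
He150,plateau,88.91,He-4,74.705,3.221
He150,plateau,88.91,H-1,25.255,1.241
He150,plateau,88.91,Li-7,3.30e-4,27.360
He150,peak,144.91,He-4,70.525,22.659
He150,peak,144.91,H-1,29.471,1.562
He150,peak,144.91,Li-7,6.29e-5,205.123
He150,falloff,148.1,He-4,1.227,56.400
He150,falloff,148.1,H-1,98.768,1.464
He150,falloff,148.1,Li-7,1.49e-5,330.995
C400,entrance,0.10,C-12,98.196,9.883
C400,entrance,0.10,H-1,1.646,2.510
C400,entrance,0.10,He-4,0.117,16.517
C400,plateau,172.24,C-12,18.948,14.972
C400,plateau,172.24,H-1,56.712,0.636
C400,plateau,172.24,He-4,18.215,1.494
C400,peak,256.9,C-12,8.031,167.429
C400,peak,256.9,H-1,61.438,0.763
C400,peak,256.9,He-4,23.790,2.455
C400,falloff,259.21,C-12,0.054,291.223
C400,falloff,259.21,H-1,66.900,0.740
C400,falloff,259.21,He-4,25.929,2.411
C290,entrance,0.10,C-12,98.600,11.985
C290,entrance,0.10,H-1,1.237,2.790
C290,entrance,0.10,He-4,0.110,15.473
C290,plateau,95.03,C-12,32.500,18.089
C290,plateau,95.03,H-1,45.839,0.836
C290,plateau,95.03,He-4,15.946,1.875
C290,peak,147.92,C-12,18.900,182.151
C290,peak,147.92,H-1,50.947,1.036
C290,peak,147.92,He-4,23.109,3.366
C290,falloff,150.15,C-12,0.0001,170.56
C290,falloff,150.15,H-1,63.010,0.981
C290,falloff,150.15,He-4,28.714,3.278
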
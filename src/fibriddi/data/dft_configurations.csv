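config_id,Eb_eV,dHL_eV,d_angstrom,contact
XII,2.40,2.02,1.84,O-H
IV,2.36,2.11,1.64,O-H
II,1.99,1.87,1.59,N-H
XIII,1.99,2.26,1.77,H-O
XIV,1.99,2.15,2.08,N-H
XI,1.97,1.63,1.59,O-H
VI,1.92,1.90,2.25,N-H
VII,1.88,2.13,2.09,H-H
X,1.84,2.29,2.12,O-H
VIII,1.83,2.30,1.80,H-O
III,1.82,2.22,2.07,H-H
I,1.76,1.47,1.84,O-H
IX,1.71,2.20,2.10,O-H
V,1.67,1.97,2.52,C-H
XV,1.67,2.21,1.91,H-H
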
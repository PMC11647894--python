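form: II
provenance: SYNTHETIC idealized template for cellulose II. Lattice constants follow
  the published fiber-diffraction unit cell of cellulose II (Langan, Nishiyama & Chanzy,
  J. Am. Chem. Soc. 2001); the atomic coordinates are an idealized chair-ring glucose
  geometry closed under the 2_1 chain screw, NOT the experimental coordinates.
cell:
  a: 8.1
  b: 9.03
  c: 10.31
  alpha: 90.0
  beta: 90.0
  gamma: 117.1
symmetry_ops:
- x,y,z
- -x,-y,z+1/2
chain_sites:
  origin:
    uv:
    - 0.0
    - 0.0
    rotation_deg: 104.42
    z_offset_frac: 0.0
    flip: false
  center:
    uv:
    - 0.5
    - 0.5
    rotation_deg: 119.51
    z_offset_frac: 0.249
    flip: true
residue_atoms:
- name: C1
  element: C
  xyz:
  - 0.1606
  - 0.4659
  - 1.904
- name: C2
  element: C
  xyz:
  - 1.112
  - 1.0027
  - 0.8366
- name: C3
  element: C
  xyz:
  - 0.444
  - 0.9954
  - -0.5253
- name: C4
  element: C
  xyz:
  - -0.0523
  - -0.4107
  - -0.8054
- name: C5
  element: C
  xyz:
  - -0.9842
  - -0.8414
  - 0.325
- name: O5
  element: O
  xyz:
  - -0.2766
  - -0.8476
  - 1.5647
- name: O2
  element: O
  xyz:
  - 1.4876
  - 2.3416
  - 1.1703
- name: O3
  element: O
  xyz:
  - 1.3882
  - 1.3819
  - -1.5274
- name: O4
  element: O
  xyz:
  - -0.855
  - -0.3826
  - -1.9996
- name: O6
  element: O
  xyz:
  - -0.441
  - -3.0751
  - -0.4098
- name: C6
  element: C
  xyz:
  - -1.5139
  - -2.2423
  - 0.0379
- name: H1
  element: H
  xyz:
  - -0.6899
  - 1.1538
  - 1.9934
- name: H2
  element: H
  xyz:
  - 2.012
  - 0.3713
  - 0.8025
- name: H3
  element: H
  xyz:
  - -0.4047
  - 1.6952
  - -0.5259
- name: H4
  element: H
  xyz:
  - 0.7945
  - -1.1131
  - -0.8202
- name: H5
  element: H
  xyz:
  - -1.8279
  - -0.1386
  - 0.39
- name: H61
  element: H
  xyz:
  - -2.2871
  - -2.1892
  - -0.7426
- name: H62
  element: H
  xyz:
  - -1.9479
  - -2.6655
  - 0.9558
- name: HO2
  element: H
  xyz:
  - 2.3002
  - 2.5547
  - 0.7057
- name: HO3
  element: H
  xyz:
  - 1.1231
  - 2.2331
  - -1.8836
- name: HO6
  element: H
  xyz:
  - -0.7429
  - -3.9864
  - -0.4111
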
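form: Ibeta
provenance: SYNTHETIC idealized template for cellulose Ibeta. Lattice constants follow
  the published fiber-diffraction unit cell of cellulose Ibeta (Nishiyama, Langan
  & Chanzy, J. Am. Chem. Soc. 2002); the atomic coordinates are an idealized chair-ring
  glucose geometry closed under the 2_1 chain screw, NOT the experimental coordinates.
cell:
  a: 7.784
  b: 8.201
  c: 10.38
  alpha: 90.0
  beta: 90.0
  gamma: 96.5
symmetry_ops:
- x,y,z
- -x,-y,z+1/2
chain_sites:
  origin:
    uv:
    - 0.0
    - 0.0
    rotation_deg: 97.9
    z_offset_frac: 0.0
    flip: false
  center:
    uv:
    - 0.5
    - 0.5
    rotation_deg: 274.74
    z_offset_frac: 0.234
    flip: false
residue_atoms:
- name: C1
  element: C
  xyz:
  - -0.0219
  - 0.4748
  - 3.4682
- name: C2
  element: C
  xyz:
  - 0.6757
  - 1.3305
  - 2.4111
- name: C3
  element: C
  xyz:
  - 0.0546
  - 1.1143
  - 1.0425
- name: C4
  element: C
  xyz:
  - 0.0868
  - -0.3704
  - 0.7306
- name: C5
  element: C
  xyz:
  - -0.6451
  - -1.1138
  - 1.8465
- name: O5
  element: O
  xyz:
  - 0.0163
  - -0.9014
  - 3.0951
- name: O2
  element: O
  xyz:
  - 0.5556
  - 2.7098
  - 2.769
- name: O3
  element: O
  xyz:
  - 0.8022
  - 1.8301
  - 0.0558
- name: O4
  element: O
  xyz:
  - -0.6741
  - -0.6063
  - -0.4741
- name: O6
  element: O
  xyz:
  - 0.6778
  - -3.1017
  - 1.4962
- name: C6
  element: C
  xyz:
  - -0.6631
  - -2.6059
  - 1.5321
- name: H1
  element: H
  xyz:
  - -1.055
  - 0.8276
  - 3.5766
- name: H2
  element: H
  xyz:
  - 1.7409
  - 1.0588
  - 2.3716
- name: H3
  element: H
  xyz:
  - -0.9866
  - 1.4692
  - 1.048
- name: H4
  element: H
  xyz:
  - 1.1266
  - -0.7301
  - 0.7268
- name: H5
  element: H
  xyz:
  - -1.6786
  - -0.7433
  - 1.9141
- name: H61
  element: H
  xyz:
  - -1.1405
  - -2.7688
  - 0.5546
- name: H62
  element: H
  xyz:
  - -1.23
  - -3.1378
  - 2.3103
- name: HO2
  element: H
  xyz:
  - 1.4363
  - 3.0676
  - 2.9028
- name: HO3
  element: H
  xyz:
  - 0.2414
  - 2.5167
  - -0.3126
- name: HO6
  element: H
  xyz:
  - 0.818
  - -3.54
  - 0.6537
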
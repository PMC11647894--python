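# GLYCAM06-style nonbonded parameters for cellulose (anhydroglucose) atoms.
# Columns: atom_name  partial_charge(e)  vdw_radius(Angstrom)  epsilon(kcal/mol)
#
# Partial charges: GLYCAM06 cellulose values; all aliphatic hydrogens and any
# atom not charged below carry charge 0, so that a central glucose unit is
# exactly neutral.
# vdw_radius is the per-atom R_i entering R_min = (R_i + R_j)/2, i.e. twice
# the AMBER/GLYCAM R*_i. Lennard-Jones radii/well depths are the GLYCAM06
# values for the glucose atom types (Cg, H1, H2, Ho, Oh, Os); this file is
# externally sourced parameter data, not a result of this package.
# Hydroxyl hydrogens (Ho type) have epsilon = 0 in GLYCAM; their radius entry
# is a nominal positive placeholder that never enters an energy because the
# geometric-mean well depth vanishes.
#
# name  charge    radius  epsilon
C1      0.384     3.8160  0.1094
C2      0.310     3.8160  0.1094
C3      0.284     3.8160  0.1094
C4      0.276     3.8160  0.1094
C5      0.225     3.8160  0.1094
C6      0.282     3.8160  0.1094
O2     -0.718     3.4420  0.2104
O3     -0.709     3.4420  0.2104
O4     -0.468     3.3674  0.1700
O5     -0.471     3.3674  0.1700
O6     -0.688     3.4420  0.2104
H1      0.000     2.5740  0.0157
H2      0.000     2.7740  0.0157
H3      0.000     2.7740  0.0157
H4      0.000     2.7740  0.0157
H5      0.000     2.7740  0.0157
H61     0.000     2.7740  0.0157
H62     0.000     2.7740  0.0157
HO2     0.437     1.2000  0.0000
HO3     0.432     1.2000  0.0000
HO6     0.424     1.2000  0.0000
# terminal decorations (reducing-end anomeric hydroxyl, non-reducing-end O4H)
O1     -0.468     3.4420  0.2104
HO1     0.437     1.2000  0.0000
HO4     0.437     1.2000  0.0000
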
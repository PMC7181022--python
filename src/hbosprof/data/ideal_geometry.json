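{
  "comment": "Engh-Huber-style ideal bond lengths (A) and angles (deg) for internal-to-Cartesian peptide construction. Sidechain rows: [atom, ref_a, ref_b, ref_c, bond, angle, torsion]; the new atom bonds to ref_c, forms angle ref_b-ref_c-atom, and torsion ref_a-ref_b-ref_c-atom. Torsion is a number in degrees, 'chi1', or 'chi1+<offset>'.",
  "backbone": {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.8,
    "omega": 180.0,
    "CA_CB": 1.53,
    "angle_N_CA_CB": 110.5,
    "torsion_C_N_CA_CB": 237.4
  },
  "sidechains": {
    "GLY": [],
    "ALA": [],
    "SER": [["OG", "N", "CA", "CB", 1.417, 111.1, "chi1"]],
    "CYS": [["SG", "N", "CA", "CB", 1.808, 113.8, "chi1"]],
    "THR": [
      ["OG1", "N", "CA", "CB", 1.433, 109.6, "chi1"],
      ["CG2", "N", "CA", "CB", 1.521, 110.5, "chi1+240"]
    ],
    "VAL": [
      ["CG1", "N", "CA", "CB", 1.521, 110.5, "chi1"],
      ["CG2", "N", "CA", "CB", 1.521, 110.5, "chi1+240"]
    ],
    "ILE": [
      ["CG1", "N", "CA", "CB", 1.53, 110.4, "chi1"],
      ["CG2", "N", "CA", "CB", 1.521, 110.5, "chi1+240"],
      ["CD1", "CA", "CB", "CG1", 1.513, 113.9, 180.0]
    ],
    "LEU": [
      ["CG", "N", "CA", "CB", 1.53, 116.3, "chi1"],
      ["CD1", "CA", "CB", "CG", 1.521, 110.7, 180.0],
      ["CD2", "CA", "CB", "CG", 1.521, 110.7, 60.0]
    ],
    "ASP": [
      ["CG", "N", "CA", "CB", 1.516, 112.6, "chi1"],
      ["OD1", "CA", "CB", "CG", 1.249, 118.4, 0.0],
      ["OD2", "CA", "CB", "CG", 1.249, 118.4, 180.0]
    ],
    "ASN": [
      ["CG", "N", "CA", "CB", 1.516, 112.6, "chi1"],
      ["OD1", "CA", "CB", "CG", 1.231, 120.8, 0.0],
      ["ND2", "CA", "CB", "CG", 1.328, 116.4, 180.0]
    ],
    "GLU": [
      ["CG", "N", "CA", "CB", 1.52, 114.1, "chi1"],
      ["CD", "CA", "CB", "CG", 1.516, 112.6, 180.0],
      ["OE1", "CB", "CG", "CD", 1.249, 118.4, 0.0],
      ["OE2", "CB", "CG", "CD", 1.249, 118.4, 180.0]
    ],
    "GLN": [
      ["CG", "N", "CA", "CB", 1.52, 114.1, "chi1"],
      ["CD", "CA", "CB", "CG", 1.516, 112.6, 180.0],
      ["OE1", "CB", "CG", "CD", 1.231, 120.8, 0.0],
      ["NE2", "CB", "CG", "CD", 1.328, 116.4, 180.0]
    ],
    "MET": [
      ["CG", "N", "CA", "CB", 1.52, 114.1, "chi1"],
      ["SD", "CA", "CB", "CG", 1.803, 112.7, 180.0],
      ["CE", "CB", "CG", "SD", 1.791, 100.9, 180.0]
    ],
    "LYS": [
      ["CG", "N", "CA", "CB", 1.52, 114.1, "chi1"],
      ["CD", "CA", "CB", "CG", 1.52, 111.3, 180.0],
      ["CE", "CB", "CG", "CD", 1.52, 111.3, 180.0],
      ["NZ", "CG", "CD", "CE", 1.489, 111.9, 180.0]
    ],
    "ARG": [
      ["CG", "N", "CA", "CB", 1.52, 114.1, "chi1"],
      ["CD", "CA", "CB", "CG", 1.52, 111.3, 180.0],
      ["NE", "CB", "CG", "CD", 1.461, 112.0, 180.0],
      ["CZ", "CG", "CD", "NE", 1.329, 124.2, 180.0],
      ["NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0],
      ["NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0]
    ],
    "HIS": [
      ["CG", "N", "CA", "CB", 1.497, 113.8, "chi1"],
      ["ND1", "CA", "CB", "CG", 1.371, 122.7, 90.0],
      ["CD2", "CA", "CB", "CG", 1.356, 131.2, 270.0],
      ["CE1", "CB", "CG", "ND1", 1.319, 109.0, 180.0],
      ["NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0]
    ],
    "PHE": [
      ["CG", "N", "CA", "CB", 1.502, 113.8, "chi1"],
      ["CD1", "CA", "CB", "CG", 1.384, 120.7, 90.0],
      ["CD2", "CA", "CB", "CG", 1.384, 120.7, 270.0],
      ["CE1", "CB", "CG", "CD1", 1.382, 120.7, 180.0],
      ["CE2", "CB", "CG", "CD2", 1.382, 120.7, 180.0],
      ["CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0]
    ],
    "TYR": [
      ["CG", "N", "CA", "CB", 1.502, 113.8, "chi1"],
      ["CD1", "CA", "CB", "CG", 1.384, 120.7, 90.0],
      ["CD2", "CA", "CB", "CG", 1.384, 120.7, 270.0],
      ["CE1", "CB", "CG", "CD1", 1.382, 120.7, 180.0],
      ["CE2", "CB", "CG", "CD2", 1.382, 120.7, 180.0],
      ["CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0],
      ["OH", "CD1", "CE1", "CZ", 1.376, 120.0, 180.0]
    ],
    "TRP": [
      ["CG", "N", "CA", "CB", 1.498, 113.6, "chi1"],
      ["CD1", "CA", "CB", "CG", 1.365, 126.9, 90.0],
      ["CD2", "CA", "CB", "CG", 1.433, 126.6, 270.0],
      ["NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0],
      ["CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0],
      ["CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0],
      ["CZ2", "CG", "CD2", "CE2", 1.398, 122.4, 180.0],
      ["CZ3", "CG", "CD2", "CE3", 1.392, 118.8, 180.0],
      ["CH2", "CD2", "CE3", "CZ3", 1.369, 121.1, 0.0]
    ],
    "PRO": [
      ["CG", "N", "CA", "CB", 1.495, 104.5, "chi1"],
      ["CD", "CA", "CB", "CG", 1.507, 106.1, 325.0]
    ]
  }
}
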
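{
  "comment": "Planar group definitions. 'members' are the heavy atoms of the delocalized pi system; 'plane' is the three-atom triple whose cross product defines the plane normal. Sidechain identities use one-letter amino acid codes. The peptide unit spans residues i/i+1; the C-terminal carboxyl requires OXT. sp3 entries are the terminal three-atom planes of saturated sidechains used as the null-expectation control.",
  "sidechain": {
    "F": {"residue": "PHE", "members": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], "plane": ["CG", "CD1", "CD2"], "aromatic": true},
    "Y": {"residue": "TYR", "members": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], "plane": ["CG", "CD1", "CD2"], "aromatic": true},
    "W": {"residue": "TRP", "members": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"], "plane": ["CD2", "CE2", "CE3"], "aromatic": true},
    "H": {"residue": "HIS", "members": ["CG", "ND1", "CD2", "CE1", "NE2"], "plane": ["CG", "ND1", "CD2"], "aromatic": true},
    "R": {"residue": "ARG", "members": ["NE", "CZ", "NH1", "NH2"], "plane": ["NE", "CZ", "NH1"], "aromatic": false},
    "Q": {"residue": "GLN", "members": ["CD", "OE1", "NE2"], "plane": ["OE1", "CD", "NE2"], "aromatic": false},
    "N": {"residue": "ASN", "members": ["CG", "OD1", "ND2"], "plane": ["OD1", "CG", "ND2"], "aromatic": false},
    "E": {"residue": "GLU", "members": ["CD", "OE1", "OE2"], "plane": ["OE1", "CD", "OE2"], "aromatic": false},
    "D": {"residue": "ASP", "members": ["CG", "OD1", "OD2"], "plane": ["OD1", "CG", "OD2"], "aromatic": false}
  },
  "peptide": {
    "members_i": ["CA", "C", "O"],
    "members_next": ["N", "CA"],
    "plane": [["O", 0], ["C", 0], ["N", 1]],
    "max_peptide_bond": 1.8
  },
  "cterm": {
    "members": ["C", "O", "OXT"],
    "plane": ["O", "C", "OXT"]
  },
  "sp3": {
    "L": {"residue": "LEU", "plane": ["CD1", "CG", "CD2"]},
    "V": {"residue": "VAL", "plane": ["CG1", "CB", "CG2"]},
    "M": {"residue": "MET", "plane": ["CE", "SD", "CG"]},
    "I": {"residue": "ILE", "plane": ["CD1", "CG1", "CB"]},
    "C": {"residue": "CYS", "plane": ["SG", "CB", "CA"]},
    "S": {"residue": "SER", "plane": ["OG", "CB", "CA"]},
    "T": {"residue": "THR", "plane": ["OG1", "CB", "CG2"]},
    "K": {"residue": "LYS", "plane": ["NZ", "CE", "CD"]}
  }
}
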
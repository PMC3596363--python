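# Designed CaNN-motif peptides: an N-terminal four-residue recognition
# segment (taken from anion-binding sites of natural proteins) fused to a
# 14-residue Aib-containing model anchoring helix (ABGY), acetylated at the
# N-terminus and amidated at the C-terminus.  `native` lists the phi/psi
# torsions (degrees) of the four motif residues as found in the parent
# crystal structures; the anchor helix is built at (-57, -47) and the
# "extended" variant sets the motif residues to (180, 180).
#
# Short 5-residue designs (SCPS*) are the first five residues of the parent
# with the same caps.
anchor_helix:
  sequence: [ALA, AIB, ALA, LYS, ALA, AIB, LYS, ALA, LYS, ALA, AIB, GLY, GLY, TYR]
  phi: -57.0
  psi: -47.0

motif_residues: [2, 3, 4]   # Calpha(-1), N(0), N(+1)

peptides:
  CPS224Ac:
    motif_sequence: [LEU, GLY, LYS, GLN]
    native:
      - [-89.1, 87.2]     # Leu1
      - [130.6, 126.7]    # Gly2
      - [-63.7, -45.1]    # Lys3
      - [-59.2, -46.7]    # Gln4
  CPS226:
    motif_sequence: [GLY, SER, ALA, LYS]
    native:
      - [-131.8, -146.2]  # Gly1
      - [-97.3, 115.6]    # Ser2
      - [-67.7, -35.0]    # Ala3
      - [-68.1, -47.8]    # Lys4
  CPS228:
    motif_sequence: [LEU, GLY, GLY, LEU]
    native:
      - [-112.9, 46.7]    # Leu1
      - [-95.1, -139.5]   # Gly2
      - [-63.0, -56.2]    # Gly3
      - [-62.1, -42.1]    # Leu4

short_peptides:
  SCPS224Ac: CPS224Ac
  SCPS226: CPS226
  SCPS228: CPS228
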
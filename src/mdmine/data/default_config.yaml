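# Default curated configuration: residue-name lexicon, engine rule table
# and MD keyword list.  Everything here is editable; load an alternative
# file with inference.load_config().
#
# residue_categories: category -> residue-name tokens (case-insensitive).
# engines: engine -> {unique: [...], ambiguous: [...]}; ambiguous
#   extensions are trusted only when the dataset metadata carries an MD
#   keyword.
# keywords: phrases matched case-insensitively as substrings over dataset
#   title + description.

residue_categories:
  protein:
    - ALA
    - ARG
    - ASN
    - ASP
    - CYS
    - GLN
    - GLU
    - GLY
    - HIS
    - ILE
    - LEU
    - LYS
    - MET
    - PHE
    - PRO
    - SER
    - THR
    - TRP
    - TYR
    - VAL
    # protonation / tautomer variants
    - HID
    - HIE
    - HIP
    - HSD
    - HSE
    - HSP
    - CYX
    - CYM
    - ASH
    - GLH
    - LYN
    - ARGN
    # caps and termini
    - ACE
    - NME
    - NMA
    - NH2
    - NHE
    # Martini backbone bead residues share amino-acid names, so the
    # all-atom tokens above cover coarse-grain proteins too.
  lipid:
    - POPC
    - POPE
    - POPS
    - POPG
    - POPA
    - POP2
    - DPPC
    - DPPE
    - DPPS
    - DPPG
    - DOPC
    - DOPE
    - DOPS
    - DOPG
    - DLPC
    - DLPE
    - DMPC
    - DMPE
    - DSPC
    - DAPC
    - PIP2
    - PIP3
    - CHOL
    - CHL1
    - ERG
    - CER
    - SM16
    - PSM
    - LPPC
    - CDL1
    - CDL2
    - TOCL
  nucleic:
    - DA
    - DC
    - DG
    - DT
    - DA5
    - DC5
    - DG5
    - DT5
    - DA3
    - DC3
    - DG3
    - DT3
    - A
    - C
    - G
    - U
    - RA
    - RC
    - RG
    - RU
    - RA5
    - RC5
    - RG5
    - RU5
    - RA3
    - RC3
    - RG3
    - RU3
    - ADE
    - CYT
    - GUA
    - THY
    - URA
  glucid:
    - GLC
    - AGLC
    - BGLC
    - GAL
    - AGAL
    - BGAL
    - MAN
    - AMAN
    - BMAN
    - FUC
    - XYL
    - SIA
    - NAG
    - NDG
    - BGN
    - GLA
    - SUC
    - TRE
    - MAL
    - CEL
    - GCU
    - IDR
  water_ions:
    - SOL
    - WAT
    - HOH
    - H2O
    - TIP3
    - TIP4
    - TIP5
    - T3P
    - T4P
    - SPC
    - SPCE
    - W      # Martini water
    - WF     # Martini antifreeze water
    - ION
    - NA
    - NA+
    - SOD
    - CL
    - CL-
    - CLA
    - K
    - K+
    - POT
    - MG
    - MG2
    - CA2
    - CAL
    - ZN
    - ZN2
    - LI
    - RB
    - CS
    - BR
    - F
    - IOD
    - CA     # calcium ion; clashes with C-alpha bead names are accepted

engines:
  gromacs:
    unique: [xtc, gro, mdp, tpr, trr, edr, itp, cpt, g96]
    ambiguous: [top, ndx]
  amber:
    unique: [prmtop, parm7, inpcrd, rst7, mdcrd, ncrst]
    ambiguous: []
  namd-charmm:
    unique: [psf, prm, rtf]
    ambiguous: [dcd, inp, crd]
  desmond:
    unique: [cms, dtr]
    ambiguous: [mae]

keywords:
  - molecular dynamics
  - md simulation
  - gromacs
  - charmm
  - namd
  - amber
  - desmond
  - martini
  - force field
  - trajectory
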
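# Diagnostic-residue panel for discriminating cyclizing (cALAS) from
# classical 5-aminolevulinate synthases.  Positions are 1-based coordinates
# in the packaged synthetic reference protein (calas_reference_synthetic.faa),
# which carries the cALAS state at every panel position.
reference_id: cALAS_ref_synthetic
reference_fasta: calas_reference_synthetic.faa
positions:
  - ref_position: 83
    classical_residue: T
    calas_residues: [S]
    weight: 1.0
    mandatory: true
  - ref_position: 149
    classical_residue: I
    calas_residues: [L, V]
    weight: 1.0
    mandatory: false
  - ref_position: 231
    classical_residue: D
    calas_residues: [T]
    weight: 1.0
    mandatory: false
  - ref_position: 365
    classical_residue: T
    calas_residues: [S]
    weight: 1.0
    mandatory: false
extended_positions: []
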
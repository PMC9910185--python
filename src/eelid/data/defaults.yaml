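# Default run configuration.
#
# Enzyme definitions follow REBASE: HinfI recognises G^ANTC, PauI (BssHII
# isoschizomer) recognises G^CGCGC; cut_offset is the 0-based top-strand
# cleavage position within the recognition window.
#
# The primer sequences below are synthetic stand-ins used by the reference
# panel generator; they are verified free of both recognition motifs on
# both strands.  Replace them with laboratory primer sequences to run the
# assay against real reference templates.
enzymes:
  HinfI: {recognition: GANTC, cut_offset: 1}
  PauI: {recognition: GCGCGC, cut_offset: 1}
marker_enzymes:
  cytb: HinfI
  "18S": PauI
primers:
  cytb:
    name: cytb_L14841_H15149
    forward: CCATCCAACATCTCAGCATG
    reverse: GCCCCTCAGAATGATATTTG
    max_mismatch: 0
  "18S":
    name: s18_SSUF_18R399
    forward: CTGGTTGATCCTGCCAGTAG
    reverse: CCGCGGCTGCTGGCACCAGA
    max_mismatch: 0
assay:
  # 100 bp sits between the smallest scored fragment (117 bp) and the
  # largest unscored one (70 bp) in the diagnostic profiles.
  visibility_threshold: 100
  band_tolerance: 0.05
  max_product_length: 5000
  scan_both_strands: true
classify:
  confirmation_identity: 0.98
survey:
  bootstrap_replicates: 1000
  seed: 1234
  confidence_level: 0.95
  excluded_states: [IL, NV, NY, TX]
trade:
  years: [2019, 2021]
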
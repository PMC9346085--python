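# Frozen demographic study conditions (generations / diploid Ne).
# These are the ground truths the validation experiments simulate under;
# see docs/methods.md for provenance and rationale.

tmvb_constant:
  NWILD: 25000      # wild effective size, constant through time
  NAC: 2500         # cultivated size after the domestication bottleneck
  NCC: 759000       # current cultivated size
  TDOM: 9700        # domestication onset (= wild/cultivated divergence)
  TEXP: 1500        # onset of the cultivated expansion
  MIGWC: 1.0e-4     # wild -> cultivated migration rate per generation

surch_ancient:
  NWILD: 25000
  NAC: 8500         # bottleneck at traditional-variety spreading
  NCC: 742000
  TDIV: 20000       # divergence from the sympatric wild relative
  TEXP: 1000
  MIGWC: 1.93e-5    # ancient epoch: 6000 to 3000 generations ago

# QC-cohort scenario: mild bottleneck so background kinship stays below
# the pruning threshold (see docs/methods.md)
qc_cohort:
  NWILD: 20000
  NAC: 15000
  NCC: 50000
  TDOM: 9700
  TEXP: 1500
  MIGWC: 1.0e-5

# four-taxon (((h1, h2), h3), out) gene-flow condition
trio:
  NE: 10000
  T12: 4000
  T3: 10000
  T4: 30000
  migration_rate: 5.0e-4
  migration_epoch: [500, 0]
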
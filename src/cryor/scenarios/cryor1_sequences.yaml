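name: cryor1_sequences
kind: sequences
seed: 40
parameters:
  # seven-letter motifs implanted at the reference anchor positions;
  # the eight published XXX variants in the RRXXXDK pattern
  motifs: [RREAEDK, RRESEDK, RRETEDK, RRDSEDK, RRDNEDK, RRDTEDK, RRGSEDK, RRGTQDK]
  n_records: 24
  mutation_rate: 0.05      # per-residue substitution probability off-anchor
  indel_rate: 0.02         # per-residue probability of a 1-3 aa indel event
  anchor_pad: 5            # indel-free zone around each anchor position
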
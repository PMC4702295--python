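# Demo pipeline configuration: a small synthetic superfamily end to end.
# Run from the repository root:
#   elkin run-all --config examples/demo.yaml
seed: 7
outdir: scratch/demo_run

simulate:
  n_groups: 4
  seqs_per_group: 40
  patterns_per_group: 5
  fg_match_prob: 0.95
  bg_match_prob: 0.05

align:
  rounds: 2
  seed_members: 10
  threshold: 25.0

cluster:
  threshold: 0.60

bpps:
  sweeps: 40
  burn_in: 20
  seeds_per_group: 3
  rho: 0.2

cha:
  display_rows: 3

tree:
  bootstrap: 100
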
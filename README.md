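# elkin

Classification of kinase-like superfamilies from their shared structural
core.

Eukaryotic protein kinases (EPKs) and the prokaryotic/eukaryotic
small-molecule kinases related to them (ELKs — aminoglycoside, choline,
methylthioribose, Kdo kinases and others) share a bi-lobal catalytic fold
but diverge in how they recognise substrates.  `elkin` is a pipeline for
working out that divergence from sequence alone, for computational
biologists studying kinase evolution and specificity:

1. **Hierarchical profile alignment** — sequences are matched to a
   hierarchy of group profiles (position-specific log-odds in bits, with
   Henikoff redundancy weighting and BLOSUM62 mixture pseudocounts) and
   mapped through a curated template onto a fixed set of *core columns*,
   with inter-block inserts carried losslessly alongside.
2. **Identity clustering** — greedy longest-first clustering at a
   fractional-identity threshold picks representatives.
3. **Bayesian partitioning with pattern selection** — given a predefined
   subgroup hierarchy with a few seed sequences per group, a Gibbs/
   Metropolis sampler jointly infers each sequence's subgroup and, for
   every node, the set of core columns and residue classes that best
   discriminate its *foreground* (the subtree's sequences) from its
   *background* (the rest of the parent's subtree).  The column score is
   the log Bayes factor `log B(c)` of separate versus shared
   beta-binomial match rates under Jeffreys priors, and a node's score is
   `Σ_c log B(c) + |pattern|·log ρ` with a geometric size prior ρ.
4. **Contrast hierarchical alignments (CHA)** — renderable summaries
   showing pattern markers, foreground/background match frequencies in
   integer tenths (`!` = 100 %), virtual sequence counts, indel lines and
   semi-log divergence bars.
5. **Consensus phylogenetics** — BLOSUM62 score distances, neighbor
   joining, column bootstrap, and the extended majority-rule consensus
   (all >50 % bipartitions plus compatible minority bipartitions in
   frequency order).
6. **Substrate-specificity rules** — the DFG+1 rule for aminoglycoside
   kinases (acidic DFG+1 → APH2, substrate pattern OH-NH2-OH; basic →
   APH3, OH-OH-NH2) and catalytic-loop basic-residue scanning.

Every stage is testable by parameter recovery: a first-class synthetic
generator plants catalytic motifs, subgroup-discriminating residues and
inserts with known truth.

## Worked example

Generate a superfamily of 4 groups × 60 sequences (5 planted
discriminating columns per group, carried at 95 % by members and 5 % by
non-members), then let the sampler rediscover the structure from 3 seed
sequences per group:

```python
import numpy as np
from elkin import (SuperfamilyConfig, generate_superfamily,
                   HierarchySpec, run_mcbpps)

cfg = SuperfamilyConfig(rng_seed=42, seqs_per_group=60)
records, master, truth = generate_superfamily(cfg)
groups = sorted(set(truth.labels.values()))
seeds = {g: [s for s, l in truth.labels.items() if l == g][:3] for g in groups}
state, report = run_mcbpps(master, HierarchySpec.flat(groups, seeds), rng_seed=1)

labels = state.assignment_labels()
print(f"assignment accuracy: "
      f"{np.mean([labels[s] == truth.labels[s] for s in master.ids]):.3f}")
for row in report[:5]:
    print(f"{row['node']}  col {row['column']:>3}  {row['residues']:<5}"
          f" fg {row['fg_match_pct']:5.1f}%  bg {row['bg_match_pct']:5.1f}%"
          f"  contrast {row['log_contrast']:.1f}")
print("planted columns G0:", sorted(c + 1 for c in truth.patterns["G0"]))
print("recovered    G0:", sorted(c + 1 for c in state.patterns["G0"]))
```

prints

```
assignment accuracy: 1.000
G0  col  11  P     fg  96.9%  bg   4.5%  contrast 96.8
G0  col  75  L     fg  96.8%  bg   5.0%  contrast 94.8
G0  col  76  N     fg  93.3%  bg   3.9%  contrast 90.8
G0  col  90  K     fg  93.6%  bg   4.5%  contrast 89.1
G0  col  42  R     fg  91.2%  bg   6.1%  contrast 78.6
planted columns G0: [11, 42, 75, 76, 90]
recovered    G0: [11, 42, 66, 75, 76, 83, 90]
```

Every sequence lands in its true group, and every planted column is
recovered with foreground match frequencies near the planted 95 % rate
against a ~5 % background; the contrast column is the log Bayes factor in
nats.  (Two extra columns, 66 and 83, cleared the size penalty in this
draw — genuine features of the sample, not of the generating model.)
`render_cha(master, state, "G0", display_ids)` turns any node into a
text or HTML contrast alignment.

The same pipeline is scriptable from the shell:

```bash
elkin run-all --config examples/demo.yaml   # simulate → align → cluster
                                            # → bpps → cha → tree → classify
```

The DFG+1 substrate rule is a plain function:

```python
>>> from elkin import classify_aph
>>> classify_aph("DFGD").label, classify_aph("DFGD").substrate_motif
('APH2', 'OH-NH2-OH')
>>> classify_aph("DNGR").label
'APH3'
```

## Layout

```
src/elkin/
  alphabet.py     shared alphabet, BLOSUM62 background, residue classes
  core.py         SequenceRecord, CoreAlignment, FASTA/A2M/Stockholm IO
  synthetic.py    superfamily generator with recorded truth
  profiles.py     weights, consensus, log-odds profiles
  hieralign.py    profile DP, template mapping, iterative refinement
  cluster.py      greedy identity clustering
  bpps.py         partitioning-with-pattern-selection sampler
  cha.py          contrast-alignment rendering, information content
  phylo.py        distances, NJ, bootstrap, extended majority consensus
  specificity.py  DFG+1 and catalytic-loop rules
  cli.py          `elkin` pipeline commands
docs/methods.md   models, defaults, numerical choices, limitations
```
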
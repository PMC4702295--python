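# Methods

`elkin` classifies kinase-like superfamilies — eukaryotic protein kinases
(EPKs) and the eukaryotic-like small-molecule kinases (ELKs) such as
aminoglycoside, choline and methylthioribose kinases — from the structural
core they share: Hanks & Hunter subdomains I–V, VIa, VIb, VII and IX.  All
computation happens in a single coordinate system, the *core columns*; the
long lineage-specific inserts between conserved blocks are carried along
as annotations but never scored.  This note records the models, the
defaults and why, the numerical choices, and what the synthetic validation
does and does not establish.

## Core alignment container

A `CoreAlignment` stores, per sequence, a residue or gap at every core
column plus insert segments keyed by the core column they follow (key −1
for a leading segment).  Reconstruction — inserts spliced between core
residues in order — must reproduce the raw sequence byte for byte; this
losslessness is asserted continuously in the test suite and holds by
construction of the mapping step.  Alignments serialise to A2M (inserts
lowercase) and Stockholm (inserts padded with `.`).

## Sequence weighting and the virtual count

Redundancy is removed with Henikoff position-based weights: at each column
a sequence receives `1/(r·n_a)` where `r` is the number of distinct
residues in the column and `n_a` the count of its own residue.  The
weights are rescaled to sum to an *effective (virtual) count*, defined as
the exponential entropy of the weight distribution aggregated over
distinct rows.  This definition was chosen over two more obvious ones
because it simultaneously (i) is invariant to duplicating every row, so
profiles built from weighted counts do not change, (ii) collapses a block
of identical sequences to one virtual sequence, and (iii) stays close to
`n` for diverse rows, so the partition sampler retains statistical power
on large alignments.  A single sequence has weight 1 and virtual count 1.

## Profiles and alignment

Profiles are per-column log-odds scores in bits,
`log2(f'(c,a)/p(a))`, where `p` is the BLOSUM62 marginal background and
`f'` smooths the weighted observed frequencies with substitution-matrix
mixture pseudocounts `g(a) = Σ_b f(b)·P(a|b)` at strength α (default 5);
the conditionals `P(a|b)` are implied by the BLOSUM62 half-bit entries.
Consensus calling is weighted majority with alphabetical tie-break; a
column more than half gapped emits a gap.

Sequences align to profiles by affine-gap dynamic programming (Gotoh;
open 11, extend 1 bit, the common substitution-search practice) in two
modes.  `local` provides the significance score: the conserved catalytic
blocks anchor the match, and a bit-score threshold (default 25 bits)
separates true members from shuffled sequences by a wide margin in the
validation data (true ≥ ~50 bits, shuffled ≤ ~19).  Mapping onto the core
then re-aligns the chosen profile `semiglobal` — every profile column
traversed, sequence flanks free — because a local alignment may trim a
weakly scoring terminal core column, and the core row must cover the full
coordinate system.  Traceback is deterministic; ties within 1e-9 prefer
insertion, then deletion, then match, which places gap runs as late in
the sequence as possible and resolves score-equivalent insert placements
to the leftmost-match convention.  The DP kernel is JIT-compiled with
numba when available, with an identical pure-Python fallback.

Classification (`best_profile`) takes the highest local score, breaking
ties toward the deeper profile in the hierarchy and then name order.  The
template alignment maps each profile's columns to root core columns;
profile columns outside the core, sequence insertions and flanks all
attach as inserts to the preceding core column.  Iterative refinement
alternates re-assignment, re-consensus and re-profiling; a group that
loses all significant members is frozen at its previous profile, and the
per-round count of changed core mappings is reported (a fixed point
reports 0 from round two).

## Identity clustering

Pairwise identity is matches over co-occupied core columns (inserts
excluded).  Clustering is greedy longest-first in the CD-HIT style: rows
join the first representative at or above the threshold (default 0.60),
otherwise found a cluster.  Deterministic; every member is at threshold
identity to its representative, and the cluster count is monotone in the
threshold.

## Bayesian partitioning with pattern selection

Given a predefined subgroup hierarchy, each non-root node has a
foreground (sequences assigned to its subtree) and a background (the rest
of its parent's subtree).  A node's *pattern* is a set of core columns,
each with a residue set drawn from a catalog of biochemical classes
({D,E}, {K,R}, {K,R,H}, {S,T}, {N,Q}, {I,L,V,M}, {F,Y,W}, {F,Y,W,H} and
singletons); every residue set must contain the node's seed-consensus
residue at that column.  The column score is the log Bayes factor
comparing separate beta-binomial foreground/background match rates
against a shared rate, under Jeffreys Beta(½,½) priors; columns where the
foreground is not enriched carry a negative sign so only enrichment can
be selected.  Counts are redundancy-weighted and real-valued; gaps count
as non-matches.  Pattern size is regularised by a geometric prior,
`log ρ` per column with ρ = 0.2.

Sampling starts from random non-seed assignments and random initial
patterns.  A sweep (a) Gibbs-resamples every non-seed sequence over the
leaves proportional to `exp(Δscore/T)` and (b) proposes, for each node
and each column in random order, the best add/remove/residue-set change,
accepted by the Metropolis rule.  Temperature decays linearly to zero
over the burn-in (default 30 of 60 sweeps), after which both phases are
greedy and the total log-score is non-decreasing; the best state visited
after burn-in is kept.  Seed sequences are never reassigned; internal
("?") nodes acquire membership through their subtrees.

**Consensus pruning.**  Because assignments are free, a single chain can
*manufacture* patterns on structureless data: it co-adapts assignments to
noise columns and retains columns whose contrast (2–24 nats in our null
experiments) exceeds any penalty that would still allow nucleation from a
random start.  `run_mcbpps` therefore runs several independent chains
(default 3) and prunes the best chain's patterns to the columns recovered
by every chain.  Genuinely discriminating columns are global attractors —
chains converge to identical optima on planted data — while manufactured
columns differ from chain to chain.  Under the validation conditions (4
groups × 100 sequences, 5 planted columns at 95%/5% match rates, 3 seeds
per group) the pruned sampler recovers every planted column and assigns
every sequence correctly, and on pattern-free data the median pattern
size per node is 0.

## Contrast hierarchical alignments

The renderer emits, per node: representative display rows; markers at the
sampler's pattern columns; foreground and background match frequencies in
integer tenths (`floor(10f)`, with `!` reserved for a weighted frequency
within 1e-9 of 100% — the bins are closed on the left); weighted
insertion and deletion frequencies per column; the virtual foreground and
background counts; and semi-logarithmic divergence bars.  A bar maps the
column's contrast per weighted foreground sequence through `log10`,
normalised so a fully conserved foreground column reaches the maximum
height; equal frequencies give height zero and the height is monotone in
the foreground frequency.  At non-pattern columns the reference residue
is the weighted foreground consensus.  Pattern-matching residues are
colored by biochemical class (acidic red, basic cyan,
hydrophobic/aromatic yellow; G, P, H unique).  Per-column information
content is `log2 20 − H` bits, pseudocount-free, for logo-style
summaries.  Text and HTML renders encode identical frequencies.

## Trees

Distances are normalised BLOSUM62 score distances over co-occupied
columns, `1 − (S − S_rand)/(S_max − S_rand)` clipped at zero, with
`S_rand` the background expectation and `S_max` the mean self-score.
Trees come from neighbor joining with deterministic tie-breaking and
negative branch lengths clamped to zero; on additive matrices NJ is exact
(property-tested to 12 taxa).  Bootstrap replicates resample core
columns with replacement, excluding columns more than half gapped; the
replicate count is a parameter with no canonical default.  Replicates are
summarised by the extended majority rule: bipartitions above 50% always
enter with their exact support percentage; the remainder are admitted
greedily in frequency order (ties by first occurrence) when compatible
with everything accepted.  Maximum-likelihood optimisation is out of
scope; the core alignment exports to relaxed PHYLIP for external ML
tools.

## Substrate-specificity rules

Motif positions come from template annotations (G-rich loop, β3 lysine,
C-helix glutamate, catalytic loop, DFG region), never from regex scans.
The DFG+1 rule: an acidic residue (D observed; E by charge-class
extrapolation, flagged) after the DFG motif calls APH2 with the
OH-NH2-OH substrate pattern; a basic residue (R observed; K extrapolated,
flagged) calls APH3 with OH-OH-NH2; anything else is unassigned.  The
label and substrate motif are a bijection by construction.  The
catalytic-loop scan reports `basic-KR` for any Lys/Arg in the annotated
span, else `basic-H` for a histidine (a weaker hint of peptide-kinase
capability), else `none`; the default annotation span starts after the
invariant HRD aspartate so the scan interrogates the position homologous
to the protein-kinase K168 rather than firing on the HRD arginine.
Annotation is independent of the partitioning stage: unassigned sequences
still receive motif calls.

## Synthetic superfamilies

The generator emulates exactly the features the pipeline exploits:
invariant catalytic-motif columns shared by all groups (G-rich glycines,
β3 K, C-helix E, HRD + Mg-binding N, DFG); per-group planted residues at
disjoint columns, carried with probability `fg_match_prob` (default 0.95)
by subtree members and `bg_match_prob` (default 0.05) by others, with the
non-carrying draw explicitly excluding the planted residue so match
frequencies are exactly binomial; i.i.d. BLOSUM62-background residues
elsewhere; and uniform-length inserts at fixed points between blocks.
Defaults: 4 flat groups × 100 sequences over 100 core columns with 5
planted columns per group — the scale at which the sampler's recovery is
validated.  Child groups inherit ancestor patterns, mirroring the
foreground-as-subtree semantics.  One seeded RNG stream makes every
output byte-reproducible.

What this does *not* model: phylogenetic substitution processes (no rate
matrices or branch lengths — groups are exchangeable), family-wide
conservation outside the planted and catalytic columns, compositional
bias, and length variation of the core itself.  Passing recovery tests
therefore demonstrates correctness of the inference machinery under its
own assumptions, not performance on real superfamilies, where
between-column correlation and clade structure make both alignment and
partitioning harder in some respects (weaker per-column signal) and
easier in others (many correlated informative columns).

## Problem sizes and numerical choices

The validation suite runs the sampler at 4×100 sequences × 100 columns
(three chains, 60 sweeps) and the null calibration at ten 4×50 datasets;
the alignment DP is verified against exhaustive enumeration up to length
8, and NJ against 100 random additive trees up to 12 taxa.  Count
arithmetic clips tiny negative values arising from incremental updates;
beta functions come from `scipy.special.betaln`; all stochastic entry
points take explicit integer seeds and are bit-reproducible.  Degenerate
inputs are defined, not special-cased: empty foregrounds score only the
size penalty, all-gap columns emit gap consensus and zero identity
contributions, and an unclassifiable sequence is a status, not an error.

## Known limitations

Consensus pruning trades recall for calibration when chains genuinely
disagree (short chains on weak signal prune aggressively); the sampler
assumes the hierarchy is given and cannot discover novel subgroups; seeds
must sit on leaf nodes; insert placement at score-equivalent boundaries
is conventional (leftmost match) rather than identifiable; and the
DFG+1 charge-class extrapolation (E/K) goes beyond the residues actually
observed in characterized enzymes — such calls are flagged in the output.
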
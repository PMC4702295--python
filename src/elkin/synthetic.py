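"""Synthetic kinase-like superfamilies with planted subgroup patterns.

The generator emulates the statistical structure the downstream stages are
built to exploit: every sequence shares invariant catalytic-motif columns
(analogs of the glycine-rich loop, the β3 lysine, the C-helix glutamate,
the HRD catalytic loop and the DFG magnesium-binding motif), each subgroup
carries *planted* discriminating residues at known core columns, and
variable-length inserts separate the conserved blocks.  Because the planted
truth is recorded, every downstream stage — alignment, clustering,
partitioning, rendering, classification — is testable by parameter
recovery.

Groups are exchangeable samples around a shared background distribution;
there is no phylogenetic substitution process.  Subgroups may nest: a child
group's sequences also carry every ancestor group's planted residues, which
mirrors the foreground-as-subtree semantics of the partition sampler.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, BACKGROUND
from .core import CoreAlignment, SequenceRecord

# Default catalytic-motif columns (0-based): G-rich loop glycines, β3
# lysine, C-helix glutamate, HRD catalytic loop + Mg-coordinating
# asparagine, and the DFG magnesium-binding motif.
DEFAULT_CATALYTIC = (
    (7, "G"), (9, "G"), (12, "G"),
    (21, "K"),
    (33, "E"),
    (66, "H"), (67, "R"), (68, "D"), (71, "N"),
    (84, "D"), (85, "F"), (86, "G"),
)

# Template motif annotations for the default layout (0-based inclusive
# spans).  The DFG-region span covers DFG plus the DFG+1 position.  The
# catalytic-loop span starts after the invariant HRD-aspartate so that
# the basic-residue scan interrogates the positions where the
# protein-kinase Lys/Arg (K168 in PKA numbering) would sit, not the HRD
# arginine itself.
DEFAULT_MOTIFS = {
    "g_rich_loop": (6, 13),
    "beta3_lysine": (21, 21),
    "c_helix_glutamate": (33, 33),
    "catalytic_loop": (69, 72),
    "dfg_region": (84, 87),
}

# Insert points between conserved blocks: after β3/C-helix, the long
# ELK-style insert between the E-helix and the catalytic loop, and a short
# C-terminal one.
DEFAULT_INSERTS = ((32, 0, 6), (63, 2, 10), (92, 0, 4))


@dataclass
class SuperfamilyConfig:
    """Study conditions for one synthetic superfamily.

    ``hierarchy`` gives the parent group index per group (``None`` = child
    of the implicit root).  Sequences are emitted for leaf groups only;
    internal groups contribute planted patterns inherited by their
    descendants.
    """

    n_groups: int = 4
    hierarchy: tuple = (None, None, None, None)
    seqs_per_group: int = 100
    core_length: int = 100
    catalytic_columns: tuple = DEFAULT_CATALYTIC
    patterns_per_group: int = 5
    fg_match_prob: float = 0.95
    bg_match_prob: float = 0.05
    insert_points: tuple = DEFAULT_INSERTS
    background_frequencies: np.ndarray = field(
        default_factory=lambda: BACKGROUND.copy()
    )
    rng_seed: int = 0
    # Optional explicit planted residues, merged over the sampled ones:
    # {group index: {column: residue}}.
    planted_patterns: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_groups < 1 or len(self.hierarchy) != self.n_groups:
            raise ValueError("hierarchy must list a parent per group")
        for g, p in enumerate(self.hierarchy):
            if p is not None and not (0 <= p < self.n_groups and p != g):
                raise ValueError(f"bad parent {p!r} for group {g}")
        if not 0.0 <= self.bg_match_prob < self.fg_match_prob <= 1.0:
            raise ValueError("need 0 <= bg_match_prob < fg_match_prob <= 1")
        cat_cols = {c for c, _ in self.catalytic_columns}
        if len(cat_cols) != len(self.catalytic_columns):
            raise ValueError("duplicate catalytic columns")
        if any(not 0 <= c < self.core_length for c in cat_cols):
            raise ValueError("catalytic column outside core")
        for g, pat in self.planted_patterns.items():
            if not 0 <= g < self.n_groups:
                raise ValueError(f"planted pattern for unknown group {g}")
            if set(pat) & cat_cols:
                raise ValueError("planted pattern overlaps catalytic columns")
        n_planted = self.n_groups * self.patterns_per_group + sum(
            len(p) for p in self.planted_patterns.values()
        )
        if self.core_length < n_planted + len(cat_cols):
            raise ValueError("core too short for planted + catalytic columns")
        for after, lo, hi in self.insert_points:
            if not -1 <= after < self.core_length:
                raise ValueError("insert point outside core")
            if not 0 <= lo <= hi:
                raise ValueError("bad insert length range")

    # -- hierarchy helpers ------------------------------------------------
    def children(self, g: int | None) -> list[int]:
        return [i for i, p in enumerate(self.hierarchy) if p == g]

    def leaves(self) -> list[int]:
        return [g for g in range(self.n_groups) if not self.children(g)]

    def ancestry(self, g: int) -> list[int]:
        """Group ``g`` and its ancestors, leaf-to-root order."""
        chain, cur = [], g
        while cur is not None:
            chain.append(cur)
            cur = self.hierarchy[cur]
            if len(chain) > self.n_groups:
                raise ValueError("hierarchy contains a cycle")
        return chain

    def group_name(self, g: int) -> str:
        return f"G{g}"


@dataclass
class SuperfamilyTruth:
    """Ground truth recorded alongside a generated superfamily."""

    labels: dict[str, str]  # seq id -> leaf group name
    patterns: dict[str, dict[int, str]]  # group name -> column -> residue
    inserts: dict[str, dict[int, str]]  # seq id -> after-column -> segment

    def to_table(self) -> str:
        lines = ["seq_id\tgroup\tpattern_columns"]
        for sid, grp in self.labels.items():
            cols = ";".join(
                f"{c + 1}{r}" for c, r in sorted(self.patterns[grp].items())
            )
            lines.append(f"{sid}\t{grp}\t{cols}")
        return "\n".join(lines) + "\n"


def _draw(rng: np.random.Generator, freqs: np.ndarray, exclude: str | None = None) -> str:
    """One residue from ``freqs``, optionally excluding one residue."""
    if exclude is None:
        return AMINO_ACIDS[rng.choice(20, p=freqs)]
    f = freqs.copy()
    f[AA_INDEX[exclude]] = 0.0
    f /= f.sum()
    return AMINO_ACIDS[rng.choice(20, p=f)]


def _draw_many(
    rng: np.random.Generator,
    freqs: np.ndarray,
    size,
    exclude: str | None = None,
) -> np.ndarray:
    """Residue codes drawn i.i.d. from ``freqs`` (optionally excluding one)."""
    if exclude is None:
        return rng.choice(20, size=size, p=freqs)
    f = freqs.copy()
    f[AA_INDEX[exclude]] = 0.0
    f /= f.sum()
    return rng.choice(20, size=size, p=f)


def generate_superfamily(
    config: SuperfamilyConfig,
) -> tuple[list[SequenceRecord], CoreAlignment, SuperfamilyTruth]:
    """Generate a superfamily: raw sequences, true alignment and truth.

    Deterministic for a fixed ``config.rng_seed``.  Match events at planted
    columns are exact Bernoulli draws: a sequence either carries the
    planted residue (probability ``fg_match_prob`` for members of the
    group's subtree, ``bg_match_prob`` otherwise) or draws a background
    residue explicitly excluding it, so empirical match frequencies are
    binomial with exactly the configured rates.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    freqs = np.asarray(config.background_frequencies, dtype=float)
    freqs = freqs / freqs.sum()
    cat = dict(config.catalytic_columns)

    # Plant discriminating columns: disjoint across groups and from the
    # catalytic columns.
    free_cols = [c for c in range(config.core_length) if c not in cat]
    explicit_cols = {
        c for pat in config.planted_patterns.values() for c in pat
    }
    pool = [c for c in free_cols if c not in explicit_cols]
    pool = list(rng.permutation(pool))
    patterns: dict[str, dict[int, str]] = {}
    for g in range(config.n_groups):
        pat = dict(config.planted_patterns.get(g, {}))
        for _ in range(config.patterns_per_group):
            pat[int(pool.pop())] = _draw(rng, freqs)
        patterns[config.group_name(g)] = pat

    # Per-group inherited pattern (own + all ancestors).
    inherited: dict[int, dict[int, str]] = {}
    for g in range(config.n_groups):
        merged: dict[int, str] = {}
        for anc in config.ancestry(g):
            merged.update(patterns[config.group_name(anc)])
        inherited[g] = merged

    ids, rows, ins_list = [], [], []
    labels: dict[str, str] = {}
    truth_inserts: dict[str, dict[int, str]] = {}
    records: list[SequenceRecord] = []

    # Any planted column belongs to exactly one group (disjoint sampling).
    planted_at: dict[int, str] = {}
    for g in range(config.n_groups):
        for c, r in patterns[config.group_name(g)].items():
            planted_at[c] = r

    for leaf in config.leaves():
        own = inherited[leaf]
        gname = config.group_name(leaf)
        m = config.seqs_per_group
        L = config.core_length
        codes = _draw_many(rng, freqs, (m, L))
        for c in range(L):
            if c in cat:
                codes[:, c] = AA_INDEX[cat[c]]
                continue
            planted_res = own.get(c, planted_at.get(c))
            if planted_res is None:
                continue
            p = config.fg_match_prob if c in own else config.bg_match_prob
            match = rng.random(m) < p
            codes[match, c] = AA_INDEX[planted_res]
            n_miss = int((~match).sum())
            if n_miss:
                codes[~match, c] = _draw_many(
                    rng, freqs, n_miss, exclude=planted_res
                )
        for k in range(m):
            sid = f"{gname}_s{k:03d}"
            inserts: dict[int, str] = {}
            for after, lo, hi in config.insert_points:
                n = int(rng.integers(lo, hi + 1))
                if n:
                    inserts[after] = "".join(
                        AMINO_ACIDS[j] for j in _draw_many(rng, freqs, n)
                    )
            ids.append(sid)
            rows.append("".join(AMINO_ACIDS[j] for j in codes[k]))
            ins_list.append(inserts)
            labels[sid] = gname
            truth_inserts[sid] = inserts

    alignment = CoreAlignment(ids, rows, ins_list)
    records = [
        SequenceRecord(sid, alignment.reconstruct(i), group=labels[sid])
        for i, sid in enumerate(ids)
    ]
    truth = SuperfamilyTruth(labels, patterns, truth_inserts)
    return records, alignment, truth


def degap(alignment: CoreAlignment) -> list[SequenceRecord]:
    """Strip core-column structure: raw sequences with inserts spliced in."""
    return alignment.degap()
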
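"""Position-specific profiles, consensus calling and redundancy weighting.

Weighting follows the Henikoff & Henikoff position-based scheme: at each
column a sequence receives ``1 / (r * n_a)`` where ``r`` is the number of
distinct residues in the column and ``n_a`` the count of the sequence's own
residue.  Raw weights are rescaled so they sum to the *effective* (virtual)
sequence count, defined as the mean over columns of the exponential of the
column's residue-composition entropy — a block of identical sequences
therefore counts as roughly one virtual sequence.

Profiles are per-column log-odds scores in bits,
``log2(f'(c, a) / p(a))``, where ``f'`` is the weighted residue frequency
smoothed with substitution-matrix mixture pseudocounts derived from
BLOSUM62 and ``p`` is the BLOSUM62 background.  Insert states are not
modelled; affine gap penalties stand in.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    BACKGROUND,
    GAP,
    blosum62_conditional,
)
from .core import CoreAlignment

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_PSEUDOCOUNT = 5.0


@dataclass
class SequenceWeights:
    """Per-sequence redundancy weights summing to the effective count."""

    weights: np.ndarray
    effective_count: float


@dataclass
class Profile:
    """Per-column log-odds scores (bits) with consensus and hierarchy link."""

    name: str
    columns: np.ndarray  # (L, 20) log-odds, bits
    consensus: str
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    parent_name: str | None = None

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("columns must be (L, 20)")
        if len(self.consensus) != self.columns.shape[0]:
            raise ValueError("consensus length != column count")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("non-finite profile scores")

    @property
    def ncols(self) -> int:
        return self.columns.shape[0]

    # -- plain-text serialisation --------------------------------------
    def to_text(self) -> str:
        lines = [
            f"# profile\t{self.name}",
            f"# parent\t{self.parent_name or '-'}",
            f"# gap_open\t{self.gap_open:g}",
            f"# gap_extend\t{self.gap_extend:g}",
            f"# consensus\t{self.consensus}",
            f"# alphabet\t{AMINO_ACIDS}",
        ]
        for row in self.columns:
            lines.append("\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "Profile":
        meta, rows = {}, []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key.strip()] = val.strip()
            else:
                rows.append([float(v) for v in line.split("\t")])
        parent = meta.get("parent", "-")
        return cls(
            name=meta["profile"],
            columns=np.array(rows, dtype=float),
            consensus=meta["consensus"],
            gap_open=float(meta.get("gap_open", DEFAULT_GAP_OPEN)),
            gap_extend=float(meta.get("gap_extend", DEFAULT_GAP_EXTEND)),
            parent_name=None if parent == "-" else parent,
        )

    @classmethod
    def read(cls, path: str | Path) -> "Profile":
        return cls.from_text(Path(path).read_text())


def position_based_weights(alignment: CoreAlignment) -> SequenceWeights:
    """Henikoff position-based weights scaled to the effective count.

    The effective (virtual) count is the exponential entropy of the
    normalised weight distribution — close to ``n`` for diverse rows,
    and pulled down when redundancy concentrates the weights on few
    distinct sequences.  A single sequence has weight 1 and effective
    count 1.
    """
    n = len(alignment)
    if n == 0:
        raise ValueError("empty alignment")
    L = alignment.core_length
    raw = np.zeros(n)
    occupied = 0
    for c in range(L):
        col = alignment.column(c)
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        occupied += 1
        r = len(counts)
        for i, ch in enumerate(col):
            if ch != GAP:
                raw[i] += 1.0 / (r * counts[ch])
    if occupied == 0:
        raise ValueError("alignment has no occupied columns")
    s = raw.sum()
    # effective count: exponential entropy over distinct-row aggregate
    # weights, so exact duplicates collapse onto one virtual sequence
    agg: dict[str, float] = {}
    for i, row in enumerate(alignment.rows):
        agg[row] = agg.get(row, 0.0) + raw[i]
    p = np.array(list(agg.values())) / s
    pos = p[p > 0]
    effective = float(np.exp(-(pos * np.log(pos)).sum()))
    weights = raw * (effective / s)
    return SequenceWeights(weights=weights, effective_count=effective)


def _column_counts(
    alignment: CoreAlignment, weights: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted residue counts (L, 20) and weighted gap counts (L,)."""
    n = len(alignment)
    L = alignment.core_length
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    counts = np.zeros((L, 20))
    gaps = np.zeros(L)
    for i, row in enumerate(alignment.rows):
        for c, ch in enumerate(row):
            j = AA_INDEX.get(ch)
            if j is None:
                gaps[c] += w[i]
            else:
                counts[c, j] += w[i]
    return counts, gaps


def consensus(
    alignment: CoreAlignment, weights: SequenceWeights | None = None
) -> str:
    """Per-column majority residue (weighted if weights are given).

    A column whose (weighted) gap frequency exceeds 50 % emits the gap
    character.  Ties between residues break in alphabetical order.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    w = weights.weights if weights is not None else None
    counts, gaps = _column_counts(alignment, w)
    out = []
    for c in range(alignment.core_length):
        total = counts[c].sum() + gaps[c]
        if total == 0 or gaps[c] > 0.5 * total:
            out.append(GAP)
        else:
            out.append(AMINO_ACIDS[int(np.argmax(counts[c]))])
    return "".join(out)


def build_profile(
    alignment: CoreAlignment,
    weights: SequenceWeights | None = None,
    pseudocount_strength: float = DEFAULT_PSEUDOCOUNT,
    name: str = "profile",
    parent_name: str | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Profile:
    """Build a log-odds profile from a group alignment.

    Per column, observed weighted frequencies ``f`` are smoothed with
    substitution-matrix mixture pseudocounts
    ``g(a) = sum_b f(b) P(a | b)`` (BLOSUM62-implied conditionals) at
    strength ``pseudocount_strength``; scores are
    ``log2(((N f + alpha g) / (N + alpha)) / p)`` with ``N`` the column's
    weighted residue count.  Empty columns fall back to the prior.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    if pseudocount_strength <= 0:
        raise ValueError("pseudocount_strength must be positive")
    w = weights.weights if weights is not None else None
    counts, _ = _column_counts(alignment, w)
    P = blosum62_conditional()  # P[a, b] = P(a | b)
    L = alignment.core_length
    scores = np.zeros((L, 20))
    alpha = pseudocount_strength
    for c in range(L):
        N = counts[c].sum()
        if N == 0:
            f_smooth = BACKGROUND
        else:
            f = counts[c] / N
            g = P @ f
            f_smooth = (N * f + alpha * g) / (N + alpha)
        scores[c] = np.log2(f_smooth / BACKGROUND)
    return Profile(
        name=name,
        columns=scores,
        consensus=consensus(alignment, weights),
        gap_open=gap_open,
        gap_extend=gap_extend,
        parent_name=parent_name,
    )
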
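"""Amino-acid alphabet, background frequencies and biochemical residue classes.

All modules share a fixed one-letter alphabet in alphabetical order.  The
background distribution is the BLOSUM62 marginal amino-acid frequency set,
which is also the matrix used for tree building, so a single substitution
model underlies profiles, pseudocounts and distances.
"""
from __future__ import annotations

import functools

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"

# BLOSUM62 marginal residue frequencies (Henikoff & Henikoff substitution
# matrix construction), renormalised to sum exactly to 1.
_B62_MARGINALS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

BACKGROUND = np.array([_B62_MARGINALS[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()

# Biochemical residue classes used both for pattern residue sets and for
# contrast-alignment coloring: charged pairs, the basic triple, the
# hydroxyl/amide pairs, hydrophobics, aromatics, and residues with unique
# chemistry as singletons.
RESIDUE_CLASSES: tuple[frozenset, ...] = (
    frozenset("DE"),
    frozenset("KR"),
    frozenset("KRH"),
    frozenset("ST"),
    frozenset("NQ"),
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("FYWH"),
    frozenset("G"),
    frozenset("P"),
    frozenset("H"),
    frozenset("C"),
    frozenset("A"),
)

# Display color per class for contrast-alignment rendering.  Acidic red,
# basic cyan, hydrophobic/aromatic yellow; H, G, P get unique colors.
CLASS_COLORS = {
    frozenset("DE"): "red",
    frozenset("KR"): "cyan",
    frozenset("KRH"): "cyan",
    frozenset("ST"): "green",
    frozenset("NQ"): "magenta",
    frozenset("ILVM"): "yellow",
    frozenset("FYW"): "yellow",
    frozenset("FYWH"): "yellow",
    frozenset("G"): "orange",
    frozenset("P"): "purple",
    frozenset("H"): "teal",
    frozenset("C"): "brown",
    frozenset("A"): "gray",
}


def residue_color(residue: str) -> str | None:
    """Color class for a single residue (smallest class containing it)."""
    best = None
    for cls in RESIDUE_CLASSES:
        if residue in cls and (best is None or len(cls) < len(best)):
            best = cls
    return CLASS_COLORS[best] if best is not None else None


def catalog_sets_containing(residue: str) -> list[frozenset]:
    """Candidate pattern residue sets anchored on ``residue``.

    A pattern residue set is either a biochemical class from the catalog or
    a singleton; every candidate must contain the anchoring residue.
    """
    if residue not in AA_INDEX:
        return []
    out = [frozenset(residue)]
    for cls in RESIDUE_CLASSES:
        if residue in cls and cls not in out:
            out.append(cls)
    return out


@functools.cache
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 log-odds scores as a (20, 20) array in alphabet order."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a][b]
    return out


@functools.cache
def blosum62_joint() -> np.ndarray:
    """Implied joint substitution probabilities q(a, b).

    Reconstructed from the half-bit log-odds entries,
    q(a, b) ∝ p(a) p(b) 2**(s(a, b) / 2), normalised to sum to 1.
    """
    s = blosum62_matrix()
    q = np.outer(BACKGROUND, BACKGROUND) * np.power(2.0, s / 2.0)
    q /= q.sum()
    return q


@functools.cache
def blosum62_conditional() -> np.ndarray:
    """Conditional substitution probabilities P[a, b] = P(a | b)."""
    q = blosum62_joint()
    return q / q.sum(axis=0, keepdims=True)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as alphabet indices; unknown residues become -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)
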
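"""Greedy identity clustering of core-domain rows.

Identity is computed over co-occupied core columns only (inserts are
excluded): matches / co-occupied count.  Clustering is greedy
longest-first in the CD-HIT style — rows are visited in order of
decreasing ungapped length and join the first existing representative at
or above the identity threshold, otherwise found a new cluster.  The
procedure is deterministic: ties in length preserve input order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .alphabet import GAP
from .core import CoreAlignment


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over co-occupied core columns."""
    if len(a) != len(b):
        raise ValueError("rows differ in core column count")
    shared = ident = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            shared += 1
            if x == y:
                ident += 1
    if shared == 0:
        warnings.warn("no co-occupied columns; identity reported as 0")
        return 0.0
    return ident / shared


@dataclass
class Cluster:
    representative: str  # seq id
    members: list[tuple[str, float]] = field(default_factory=list)  # (id, identity to rep)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    clusters: list[Cluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def representatives(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def labels(self) -> dict[str, int]:
        return {
            sid: k
            for k, c in enumerate(self.clusters)
            for sid, _ in c.members
        }

    def to_table(self) -> str:
        lines = ["cluster_id\tis_representative\tseq_id\tidentity_to_rep"]
        for k, c in enumerate(self.clusters):
            for sid, ident in c.members:
                rep = int(sid == c.representative)
                lines.append(f"{k}\t{rep}\t{sid}\t{ident:.4f}")
        return "\n".join(lines) + "\n"


def greedy_cluster(
    alignment: CoreAlignment, threshold: float = 0.60
) -> Clustering:
    """Cluster rows at a fractional-identity threshold, longest first."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(
        range(len(alignment)),
        key=lambda i: -sum(1 for ch in alignment.rows[i] if ch != GAP),
    )
    clusters: list[Cluster] = []
    rep_rows: list[str] = []
    for i in order:
        row = alignment.rows[i]
        sid = alignment.ids[i]
        placed = False
        for c, rep_row in zip(clusters, rep_rows):
            ident = pairwise_identity(row, rep_row)
            if ident >= threshold:
                c.members.append((sid, ident))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sid, [(sid, 1.0)]))
            rep_rows.append(row)
    return Clustering(clusters, threshold)
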
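"""Core containers: sequence records and core-column alignments.

The coordinate system of the whole package is the fixed set of *core
columns* of the superfamily (the structurally shared subdomains of the
kinase fold).  A :class:`CoreAlignment` stores, per sequence, a residue or
gap at every core column plus the inter-block insert segments, keyed by the
core column they follow.  Reconstructing a row (inserts spliced between
core residues, in order) reproduces the raw sequence exactly; that
losslessness is the central invariant of the container.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alphabet import GAP


@dataclass
class SequenceRecord:
    """A protein sequence with an optional known-group label."""

    id: str
    seq: str
    group: str | None = None
    description: str = ""


class CoreAlignment:
    """Sequences mapped to a fixed set of core columns.

    Parameters
    ----------
    ids
        Per-row sequence identifiers.
    rows
        Per-row strings of length ``core_length`` over residues and ``-``.
    inserts
        Per-row mapping ``after-column -> residue string``.  Key ``-1``
        holds residues preceding the first core column; key ``L - 1`` holds
        residues trailing the last one.
    provenance
        Optional per-row ``(profile name, bit score)`` of the profile the
        row was aligned through.
    """

    def __init__(
        self,
        ids: Sequence[str],
        rows: Sequence[str],
        inserts: Sequence[dict[int, str]] | None = None,
        provenance: Sequence[tuple[str, float] | None] | None = None,
    ):
        ids = list(ids)
        rows = list(rows)
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if rows:
            L = len(rows[0])
            for r in rows:
                if len(r) != L:
                    raise ValueError("rows differ in core column count")
        self.ids = ids
        self.rows = rows
        self.inserts = [dict(d) for d in inserts] if inserts is not None else [
            {} for _ in rows
        ]
        if len(self.inserts) != len(rows):
            raise ValueError("inserts and rows differ in length")
        for d in self.inserts:
            for k, seg in d.items():
                if not (-1 <= k < self.core_length):
                    raise ValueError(f"insert key {k} outside core columns")
                if not seg:
                    raise ValueError("empty insert segment stored")
        self.provenance = (
            list(provenance) if provenance is not None else [None] * len(rows)
        )
        self._index = {sid: i for i, sid in enumerate(ids)}

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.rows)

    @property
    def core_length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_index(self, seq_id: str) -> int:
        return self._index[seq_id]

    def column(self, c: int) -> str:
        """All row characters at core column ``c``."""
        return "".join(r[c] for r in self.rows)

    def reconstruct(self, i: int) -> str:
        """Rebuild row ``i``'s raw sequence: core residues plus inserts."""
        parts = [self.inserts[i].get(-1, "")]
        for c, ch in enumerate(self.rows[i]):
            if ch != GAP:
                parts.append(ch)
            parts.append(self.inserts[i].get(c, ""))
        return "".join(parts)

    def degap(self) -> list[SequenceRecord]:
        """Raw sequences for every row (the reconstruction of each row)."""
        if not self.rows:
            raise ValueError("empty alignment")
        return [
            SequenceRecord(sid, self.reconstruct(i))
            for i, sid in enumerate(self.ids)
        ]

    def subset(self, indices: Iterable[int]) -> "CoreAlignment":
        idx = list(indices)
        return CoreAlignment(
            [self.ids[i] for i in idx],
            [self.rows[i] for i in idx],
            [self.inserts[i] for i in idx],
            [self.provenance[i] for i in idx],
        )

    # -- serialisation --------------------------------------------------
    def to_a2m(self) -> str:
        """A2M text: core columns uppercase/'-', inserts lowercase."""
        chunks = []
        for i, sid in enumerate(self.ids):
            parts = [self.inserts[i].get(-1, "").lower()]
            for c, ch in enumerate(self.rows[i]):
                parts.append(ch)
                parts.append(self.inserts[i].get(c, "").lower())
            chunks.append(f">{sid}\n{''.join(parts)}\n")
        return "".join(chunks)

    def write_a2m(self, path: str | Path) -> None:
        Path(path).write_text(self.to_a2m())

    def to_stockholm(self) -> str:
        """Stockholm text with insert regions padded by ``.``."""
        L = self.core_length
        pad = {k: 0 for k in range(-1, L)}
        for d in self.inserts:
            for k, seg in d.items():
                pad[k] = max(pad[k], len(seg))
        width = max((len(s) for s in self.ids), default=1) + 2
        lines = ["# STOCKHOLM 1.0", ""]
        for i, sid in enumerate(self.ids):
            parts = []
            for k in range(-1, L):
                if k >= 0:
                    parts.append(self.rows[i][k])
                if pad[k]:
                    seg = self.inserts[i].get(k, "").lower()
                    parts.append(seg + "." * (pad[k] - len(seg)))
            lines.append(f"{sid:<{width}}{''.join(parts)}")
        lines.append("//")
        return "\n".join(lines) + "\n"

    def write_stockholm(self, path: str | Path) -> None:
        Path(path).write_text(self.to_stockholm())

    @classmethod
    def from_a2m(cls, text: str) -> "CoreAlignment":
        """Parse A2M/aligned-FASTA (lowercase and ``.`` are insert states)."""
        ids, rows, inserts = [], [], []
        for name, body in _iter_fasta(text):
            core: list[str] = []
            ins: dict[int, str] = {}
            for ch in body:
                if ch == ".":
                    continue
                if ch.islower():
                    k = len(core) - 1
                    ins[k] = ins.get(k, "") + ch.upper()
                else:
                    core.append(ch)
            ids.append(name)
            rows.append("".join(core))
            inserts.append(ins)
        return cls(ids, rows, inserts)

    @classmethod
    def read_a2m(cls, path: str | Path) -> "CoreAlignment":
        return cls.from_a2m(Path(path).read_text())


def _iter_fasta(text: str):
    name, body = None, []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                yield name, "".join(body)
            name = line[1:].split()[0]
            body = []
        else:
            body.append(line)
    if name is not None:
        yield name, "".join(body)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
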
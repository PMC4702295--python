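"""Contrast hierarchical alignment (CHA) rendering.

A CHA displays a handful of representative foreground sequences over the
core columns, annotated with: markers at the sampler's pattern positions;
foreground and background residue frequencies in integer tenths (``!``
for exactly 100 %); the virtual (redundancy-weighted) sequence counts;
insertion and deletion frequencies per position; semi-logarithmic bars
quantifying foreground/background divergence; and biochemical coloring of
pattern-matching residues.  Per-column information content (in bits) is
provided for logo-style summaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, GAP, residue_color
from .bpps import PartitionState, column_contrast
from .core import CoreAlignment

_EXACT_TOL = 1e-9


def freq_to_glyph(freq: float) -> str:
    """Integer-tenths glyph: floor(10 f) as a digit; exactly 1.0 is ``!``."""
    if not -_EXACT_TOL <= freq <= 1.0 + _EXACT_TOL:
        raise ValueError(f"frequency {freq!r} outside [0, 1]")
    if freq >= 1.0 - _EXACT_TOL:
        return "!"
    return str(min(9, int(math.floor(10.0 * max(freq, 0.0)))))


def indel_glyphs(
    alignment: CoreAlignment, column: int, weights: np.ndarray | None = None
) -> tuple[str, str]:
    """(insertion, deletion) glyphs at a core column.

    Insertion frequency is the weighted fraction of rows carrying an
    insert *after* the column; deletion frequency the weighted fraction
    gapped at the column.  Both pass through :func:`freq_to_glyph`.
    """
    n = len(alignment)
    if not 0 <= column < alignment.core_length:
        raise ValueError("column outside core")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    ins = sum(
        w[i] for i in range(n) if alignment.inserts[i].get(column)
    )
    dels = sum(w[i] for i in range(n) if alignment.rows[i][column] == GAP)
    return freq_to_glyph(ins / total), freq_to_glyph(dels / total)


def bar_height(
    fg_freq: float,
    bg_freq: float,
    max_height: float = 9.0,
    fg_total: float = 100.0,
    bg_total: float = 1000.0,
) -> float:
    """Semi-logarithmic divergence bar for one column.

    The contrast (per weighted foreground sequence) of the column's match
    frequencies is mapped through ``log10`` onto ``[0, max_height]``,
    normalised so that a fully conserved foreground column (fg = 1)
    against the same background reaches the maximum.  Equal frequencies
    give height 0; the height is monotone increasing in ``fg_freq`` for
    fixed ``bg_freq``.
    """
    if not (0.0 <= fg_freq <= 1.0 and 0.0 <= bg_freq <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    c = column_contrast(
        fg_freq * fg_total, fg_total, bg_freq * bg_total, bg_total
    ) / fg_total
    if c <= 0.0:
        return 0.0
    cref = column_contrast(
        fg_total, fg_total, bg_freq * bg_total, bg_total
    ) / fg_total
    if cref <= 0.0:
        return 0.0
    h = max_height * math.log10(1.0 + 9.0 * min(c / cref, 1.0))
    return float(min(max(h, 0.0), max_height))


def column_information(counts) -> float:
    """Information content of a column in bits: log2(20) − H.

    ``counts`` is a residue → (weighted) count mapping or a length-20
    array in alphabet order; no pseudocounts are applied.
    """
    if isinstance(counts, dict):
        arr = np.zeros(20)
        for r, v in counts.items():
            arr[AA_INDEX[r]] += v
    else:
        arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("empty counts")
    p = arr[arr > 0] / total
    entropy = float(-(p * np.log2(p)).sum())
    return math.log2(20.0) - entropy


@dataclass
class CHADocument:
    """Renderable contrast alignment for one hierarchy node."""

    node: str
    display_ids: list[str]
    display_rows: list[str]
    marker_columns: list[int]  # 0-based pattern columns
    fg_line: str
    bg_line: str
    ins_line: str
    del_line: str
    bar_heights: list[float]
    colors: list[list[str | None]]  # per display row, per column
    fg_count: int
    bg_count: int
    fg_weighted: float
    bg_weighted: float
    pattern: dict[int, frozenset] = field(default_factory=dict)

    @property
    def ncols(self) -> int:
        return len(self.fg_line)

    def _ruler(self) -> str:
        out = [" "] * self.ncols
        for c in range(0, self.ncols, 10):
            label = str(c + 1)
            for k, ch in enumerate(label):
                if c + k < self.ncols:
                    out[c + k] = ch
        return "".join(out)

    def _marker_line(self) -> str:
        return "".join(
            "*" if c in set(self.marker_columns) else " "
            for c in range(self.ncols)
        )

    def _bar_line(self) -> str:
        return "".join(
            " " if h <= 0 else str(min(9, int(round(h))))
            for h in self.bar_heights
        )

    def lines(self) -> list[tuple[str, str]]:
        out = [
            ("ruler", self._ruler()),
            ("bars", self._bar_line()),
            ("pattern", self._marker_line()),
        ]
        out += list(zip(self.display_ids, self.display_rows))
        out += [
            ("fg", self.fg_line),
            ("bg", self.bg_line),
            ("ins", self.ins_line),
            ("del", self.del_line),
        ]
        return out

    def to_text(self) -> str:
        width = max(
            [len(tag) for tag, _ in self.lines()] + [7]
        ) + 2
        head = [
            f"# CHA node={self.node}",
            f"# foreground: {self.fg_count} seqs ({self.fg_weighted:.1f} weighted)"
            f"  background: {self.bg_count} seqs ({self.bg_weighted:.1f} weighted)",
            f"# pattern columns (1-based): "
            + ",".join(str(c + 1) for c in sorted(self.marker_columns)),
        ]
        body = [f"{tag:<{width}}{line}" for tag, line in self.lines()]
        return "\n".join(head + body) + "\n"

    def to_html(self) -> str:
        palette = {
            "red": "#d62728", "cyan": "#17becf", "yellow": "#bcbd22",
            "green": "#2ca02c", "magenta": "#e377c2", "orange": "#ff7f0e",
            "purple": "#9467bd", "teal": "#008080", "brown": "#8c564b",
            "gray": "#7f7f7f",
        }
        width = max([len(t) for t, _ in self.lines()] + [7]) + 2
        out = [
            "<html><body><pre>",
            f"# CHA node={self.node}",
            f"# foreground: {self.fg_count} seqs ({self.fg_weighted:.1f} weighted)"
            f"  background: {self.bg_count} seqs ({self.bg_weighted:.1f} weighted)",
        ]
        row_colors = dict(zip(self.display_ids, self.colors))
        for tag, line in self.lines():
            if tag in row_colors:
                cells = []
                for c, ch in enumerate(line):
                    color = row_colors[tag][c]
                    if color:
                        cells.append(
                            f'<span style="color:{palette[color]}">{ch}</span>'
                        )
                    else:
                        cells.append(ch)
                out.append(f"{tag:<{width}}" + "".join(cells))
            else:
                out.append(f"{tag:<{width}}{line}")
        out.append("</pre></body></html>")
        return "\n".join(out) + "\n"


def render_cha(
    master: CoreAlignment,
    state: PartitionState,
    node: str,
    display_ids: list[str],
    max_bar: float = 9.0,
) -> CHADocument:
    """Assemble the CHA document for one node of the hierarchy.

    The foreground is the node's subtree, the background the rest of the
    parent's subtree; frequencies are redundancy-weighted.  At pattern
    columns the reference residue set is the sampler's; elsewhere it is
    the weighted foreground consensus residue.
    """
    if master is not state.master:
        raise ValueError("state was built on a different master alignment")
    if node not in state.patterns:
        raise ValueError(f"node {node!r} has no pattern (is it the root?)")
    fg_idx = set(state.foreground_indices(node).tolist())
    for sid in display_ids:
        if master.row_index(sid) not in fg_idx:
            raise ValueError(f"display sequence {sid!r} not in foreground")
    pattern = dict(state.patterns[node])
    fg = state.fg_mask[node]
    bg = state._parent_mask(node) & ~fg
    w = state.w
    fgT, bgT = float(w[fg].sum()), float(w[bg].sum())
    L = master.core_length

    ref_sets: list[frozenset | None] = []
    for c in range(L):
        if c in pattern:
            ref_sets.append(pattern[c])
        else:
            counts = np.bincount(
                state.codes[fg, c].astype(np.int64), weights=w[fg], minlength=21
            )[:20]
            ref_sets.append(
                frozenset(AMINO_ACIDS[int(np.argmax(counts))])
                if counts.sum() > 0
                else None
            )

    fg_freq, bg_freq = np.zeros(L), np.zeros(L)
    for c, rset in enumerate(ref_sets):
        if rset is None:
            continue
        m = state._match_vec(c, rset)
        fg_freq[c] = float(w[fg & m].sum()) / fgT if fgT > 0 else 0.0
        bg_freq[c] = float(w[bg & m].sum()) / bgT if bgT > 0 else 0.0

    fg_rows = np.flatnonzero(fg)
    fg_sub = master.subset(fg_rows)
    ins_line, del_line = [], []
    for c in range(L):
        i_g, d_g = indel_glyphs(fg_sub, c, weights=w[fg_rows])
        ins_line.append(i_g)
        del_line.append(d_g)

    bars = [
        bar_height(
            fg_freq[c], bg_freq[c], max_height=max_bar,
            fg_total=max(fgT, 1e-9), bg_total=max(bgT, 1e-9),
        )
        for c in range(L)
    ]

    display_rows = [master.rows[master.row_index(sid)] for sid in display_ids]
    colors: list[list[str | None]] = []
    for row in display_rows:
        row_col: list[str | None] = []
        for c, ch in enumerate(row):
            if c in pattern and ch in pattern[c]:
                row_col.append(residue_color(ch))
            else:
                row_col.append(None)
        colors.append(row_col)

    return CHADocument(
        node=node,
        display_ids=list(display_ids),
        display_rows=display_rows,
        marker_columns=sorted(pattern),
        fg_line="".join(freq_to_glyph(f) for f in fg_freq),
        bg_line="".join(freq_to_glyph(f) for f in bg_freq),
        ins_line="".join(ins_line),
        del_line="".join(del_line),
        bar_heights=bars,
        colors=colors,
        fg_count=int(fg.sum()),
        bg_count=int(bg.sum()),
        fg_weighted=fgT,
        bg_weighted=bgT,
        pattern=pattern,
    )
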
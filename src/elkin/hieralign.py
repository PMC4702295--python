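"""Hierarchical profile alignment and mapping to the structural core.

Database sequences are aligned to a hierarchy of position-specific
profiles, each sequence to its highest-scoring profile, and then mapped
through a curated template alignment onto the shared core columns.  The
template row of each profile places that profile's columns over the root
(core) columns; profile columns falling outside the core become inserts
attached to the preceding core column.

Alignment is affine-gap dynamic programming (Gotoh) against profile
log-odds columns, in bits.  Two modes are provided: ``local``
(Smith–Waterman-style, used for significance scoring) and ``semiglobal``
(profile fully traversed, sequence flanks free; used when mapping
sequences onto the core so that weakly scoring terminal core columns are
not trimmed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP, encode
from .core import CoreAlignment, SequenceRecord
from .profiles import Profile, SequenceWeights, build_profile, consensus, position_based_weights

DEFAULT_BIT_THRESHOLD = 25.0

_NEG = -1.0e30


def _gotoh_kernel(S, gap_open, gap_extend, local):
    m, L = S.shape
    H = np.zeros((m + 1, L + 1))
    E = np.full((m + 1, L + 1), _NEG)
    F = np.full((m + 1, L + 1), _NEG)
    if not local:
        for j in range(1, L + 1):
            H[0, j] = -(gap_open + gap_extend * j)
            F[0, j] = H[0, j]
    for i in range(1, m + 1):
        for j in range(1, L + 1):
            e = H[i - 1, j] - gap_open - gap_extend
            if E[i - 1, j] - gap_extend > e:
                e = E[i - 1, j] - gap_extend
            E[i, j] = e
            f = H[i, j - 1] - gap_open - gap_extend
            if F[i, j - 1] - gap_extend > f:
                f = F[i, j - 1] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _gotoh = njit(cache=False)(_gotoh_kernel)
except Exception:  # pragma: no cover
    _gotoh = _gotoh_kernel


@dataclass
class PairwiseAlignment:
    """A sequence aligned to a profile: matched (seq index, column) pairs."""

    seq_id: str
    profile_name: str
    score: float
    pairs: list[tuple[int, int]]
    ncols: int
    mode: str = "local"


def _score_matrix(seq: str, profile: Profile) -> np.ndarray:
    codes = encode(seq)
    safe = np.where(codes >= 0, codes, 0)
    S = profile.columns[:, safe].T.copy()
    S[codes < 0, :] = 0.0
    return np.ascontiguousarray(S)


def align_to_profile(
    seq: SequenceRecord | str, profile: Profile, mode: str = "local"
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of a sequence against a profile.

    ``local`` finds the best-scoring subalignment (score floor 0);
    ``semiglobal`` traverses every profile column, charging terminal
    deletions, with free sequence flanks.  Deterministic traceback prefers
    match over deletion over insertion.
    """
    if mode not in ("local", "semiglobal"):
        raise ValueError(f"unknown mode {mode!r}")
    sid = seq.id if isinstance(seq, SequenceRecord) else "query"
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if len(s) < 1:
        raise ValueError("empty sequence")
    S = _score_matrix(s, profile)
    m, L = S.shape
    go, ge = profile.gap_open, profile.gap_extend
    H, E, F = _gotoh(S, go, ge, mode == "local")
    if mode == "local":
        flat = int(np.argmax(H))
        i, j = divmod(flat, L + 1)
        score = float(H[i, j])
    else:
        i = int(np.argmax(H[:, L]))
        j = L
        score = float(H[i, L])
    pairs: list[tuple[int, int]] = []
    state = "H"
    # Tolerance absorbs summation-order noise so that exact-score ties
    # break by the stated preference, not by floating-point ulps.
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            if mode == "local" and H[i, j] <= tol:
                break
            if i == 0 or j == 0:
                break
            # On ties prefer gaps over the match: the traceback runs
            # right-to-left, so this pushes gap runs as late in the
            # sequence as possible and matches residues leftmost.
            if abs(H[i, j] - E[i, j]) <= tol:
                state = "E"
            elif abs(H[i, j] - F[i, j]) <= tol:
                state = "F"
            elif abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= tol:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            else:  # boundary value in semiglobal mode
                break
        elif state == "F":
            if abs(H[i, j - 1] - go - ge - F[i, j]) <= tol:
                state = "H"
            j -= 1
        else:  # "E"
            if abs(H[i - 1, j] - go - ge - E[i, j]) <= tol:
                state = "H"
            i -= 1
    pairs.reverse()
    return PairwiseAlignment(sid, profile.name, score, pairs, L, mode)


def best_profile(
    seq: SequenceRecord | str,
    profiles: dict[str, Profile],
    threshold: float = DEFAULT_BIT_THRESHOLD,
    depths: dict[str, int] | None = None,
    mode: str = "local",
) -> tuple[str | None, float, PairwiseAlignment | None]:
    """Highest-scoring profile for a sequence, or unclassified.

    Ties break toward the deeper profile in the hierarchy, then by name
    order.  A best score below ``threshold`` (bits) yields
    ``(None, score, None)`` — unclassified is a status, not an error.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    depths = depths or {}
    best: tuple[str, float, PairwiseAlignment] | None = None
    for name in sorted(profiles):
        aln = align_to_profile(seq, profiles[name], mode=mode)
        if best is None:
            best = (name, aln.score, aln)
            continue
        b_name, b_score, _ = best
        if aln.score > b_score or (
            aln.score == b_score
            and depths.get(name, 0) > depths.get(b_name, 0)
        ):
            best = (name, aln.score, aln)
    name, score, aln = best
    if score < threshold:
        return None, score, None
    return name, score, aln


class TemplateAlignment:
    """Curated alignment of profile consensi over the core columns.

    ``rows`` map each profile name to a string over the template's display
    columns; the root profile's non-gap positions define the core columns
    (the root row has no gaps there).  ``parents`` give the hierarchy
    (child -> parent, root -> ``None``).  ``motifs`` optionally annotate
    named core-column spans (0-based, inclusive) such as the catalytic
    loop or the DFG region.
    """

    def __init__(
        self,
        rows: dict[str, str],
        parents: dict[str, str | None],
        motifs: dict[str, tuple[int, int]] | None = None,
    ):
        if set(rows) != set(parents):
            raise ValueError("rows and parents must name the same profiles")
        roots = [n for n, p in parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError("template must have exactly one root profile")
        self.root = roots[0]
        D = {len(r) for r in rows.values()}
        if len(D) != 1:
            raise ValueError("template rows differ in display length")
        self.rows = dict(rows)
        self.parents = dict(parents)
        self.motifs = dict(motifs or {})
        root_row = rows[self.root]
        self._core_display = [
            d for d, ch in enumerate(root_row) if ch not in (GAP, ".")
        ]
        self._core_of_display = {d: c for c, d in enumerate(self._core_display)}

    @property
    def core_length(self) -> int:
        return len(self._core_display)

    def depth(self, name: str) -> int:
        d, cur = 0, name
        while self.parents[cur] is not None:
            cur = self.parents[cur]
            d += 1
            if d > len(self.parents):
                raise ValueError("cycle in template hierarchy")
        return d

    def depths(self) -> dict[str, int]:
        return {n: self.depth(n) for n in self.rows}

    def col_map(self, name: str, ncols: int) -> list[int]:
        """Map profile columns to core columns (-1 = insert vs the root)."""
        if name not in self.rows:
            raise KeyError(f"profile {name!r} absent from template")
        row = self.rows[name]
        occupied = [d for d, ch in enumerate(row) if ch not in (GAP, ".")]
        if ncols == len(occupied):
            return [self._core_of_display.get(d, -1) for d in occupied]
        if ncols == self.core_length:
            return list(range(self.core_length))
        raise ValueError(
            f"profile {name!r} has {ncols} columns; template row covers "
            f"{len(occupied)} (core length {self.core_length})"
        )


def map_to_core(
    aln: PairwiseAlignment, template: TemplateAlignment, seq: str
) -> tuple[str, dict[int, str]]:
    """Transfer a profile alignment onto the core columns.

    Residues matched to profile columns are carried through the template's
    column map; residues in insertions, sequence flanks, or template
    insert columns attach to the preceding core column (key ``-1`` before
    the first).  The resulting row reconstructs the input exactly.
    """
    cmap = template.col_map(aln.profile_name, aln.ncols)
    L = template.core_length
    prev_core = []
    last = -1
    for c in cmap:
        if c >= 0:
            last = c
        prev_core.append(last)
    row = [GAP] * L
    inserts: dict[int, str] = {}

    def attach(key: int, chunk: str) -> None:
        if chunk:
            inserts[key] = inserts.get(key, "") + chunk

    if not aln.pairs:
        attach(-1, seq)
        return "".join(row), inserts
    i0, j0 = aln.pairs[0]
    lead_key = cmap[j0] - 1 if cmap[j0] >= 0 else prev_core[j0]
    attach(lead_key, seq[:i0])
    cur = lead_key
    prev_i = i0 - 1
    for i, j in aln.pairs:
        attach(cur, seq[prev_i + 1 : i])
        c = cmap[j]
        if c >= 0:
            row[c] = seq[i]
            cur = c
        else:
            attach(prev_core[j], seq[i])
            cur = prev_core[j]
        prev_i = i
    attach(cur, seq[prev_i + 1 :])
    return "".join(row), inserts


@dataclass
class IterationResult:
    profiles: dict[str, Profile]
    master: CoreAlignment
    change_counts: list[int]
    unclassified: list[str] = field(default_factory=list)
    template: TemplateAlignment | None = None


def template_from_groups(
    group_alignments: dict[str, CoreAlignment],
    parents: dict[str, str | None] | None = None,
    root_name: str = "root",
    motifs: dict[str, tuple[int, int]] | None = None,
) -> TemplateAlignment:
    """Build a root-anchored template from group alignments.

    The root row is the unweighted consensus over all groups pooled; each
    group row is its own consensus.  All rows span the full core, so the
    column maps are the identity.
    """
    names = sorted(group_alignments)
    pooled = CoreAlignment(
        [sid for g in names for sid in group_alignments[g].ids],
        [r for g in names for r in group_alignments[g].rows],
    )
    root_row = consensus(pooled).replace(GAP, "X")
    rows = {root_name: root_row}
    par: dict[str, str | None] = {root_name: None}
    for g in names:
        rows[g] = consensus(group_alignments[g])
        par[g] = root_name if parents is None else parents.get(g, root_name)
    return TemplateAlignment(rows, par, motifs)


def align_and_map(
    seq: SequenceRecord,
    profiles: dict[str, Profile],
    template: TemplateAlignment,
    threshold: float = DEFAULT_BIT_THRESHOLD,
    mode: str = "semiglobal",
) -> tuple[str | None, float, str | None, dict[int, str] | None]:
    """Classify one sequence and map it onto the core columns.

    Significance and profile choice use the *local* bit score (the match
    is anchored on the conserved blocks); the chosen profile is then
    re-aligned in ``mode`` (semiglobal by default) so that every core
    column is traversed when transferring the sequence onto the core.
    """
    name, score, aln = best_profile(
        seq, profiles, threshold=threshold, depths=template.depths(), mode="local"
    )
    if name is None:
        return None, score, None, None
    if mode != "local":
        aln = align_to_profile(seq, profiles[name], mode=mode)
    row, inserts = map_to_core(aln, template, seq.seq)
    return name, score, row, inserts


def iterate_profiles(
    seed_alignments: dict[str, CoreAlignment],
    sequences: list[SequenceRecord],
    n_rounds: int,
    template: TemplateAlignment | None = None,
    pseudocount_strength: float = 5.0,
    threshold: float = DEFAULT_BIT_THRESHOLD,
    mode: str = "semiglobal",
) -> IterationResult:
    """Iterative profile refinement (align / re-consensus / re-profile).

    Each round re-assigns every sequence to its best-scoring group
    profile, maps it to the core, rebuilds the group alignments and their
    profiles, and records how many core mappings changed relative to the
    previous round (round one counts every sequence as new).  A group that
    loses all significant members is frozen at its previous profile.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if template is None:
        template = template_from_groups(seed_alignments)

    def _profiles_from(alns: dict[str, CoreAlignment]) -> dict[str, Profile]:
        out = {}
        for g, aln in alns.items():
            w = position_based_weights(aln)
            out[g] = build_profile(
                aln,
                weights=w,
                pseudocount_strength=pseudocount_strength,
                name=g,
                parent_name=template.parents.get(g, template.root),
            )
        return out

    profiles = _profiles_from(seed_alignments)
    prev_map: dict[str, tuple] | None = None
    change_counts: list[int] = []
    unclassified: list[str] = []
    mappings: dict[str, tuple] = {}

    for _ in range(n_rounds):
        mappings = {}
        unclassified = []
        for seq in sequences:
            name, score, row, inserts = align_and_map(
                seq, profiles, template, threshold=threshold, mode=mode
            )
            if name is None:
                unclassified.append(seq.id)
            else:
                mappings[seq.id] = (name, score, row, inserts)
        changed = 0
        for sid, (_, _, row, inserts) in mappings.items():
            old = prev_map.get(sid) if prev_map else None
            if old is None or (old[2], old[3]) != (row, inserts):
                changed += 1
        if prev_map:
            changed += sum(1 for sid in prev_map if sid not in mappings)
        change_counts.append(changed)
        prev_map = mappings

        new_groups: dict[str, CoreAlignment] = {}
        for g in profiles:
            members = [
                (sid, row, inserts)
                for sid, (name, _, row, inserts) in mappings.items()
                if name == g
            ]
            if not members:
                warnings.warn(
                    f"group {g!r} lost all significant members; profile frozen"
                )
                continue
            new_groups[g] = CoreAlignment(
                [m[0] for m in members],
                [m[1] for m in members],
                [m[2] for m in members],
            )
        refreshed = _profiles_from(new_groups)
        profiles = {**profiles, **refreshed}

    order = [s.id for s in sequences if s.id in mappings]
    master = CoreAlignment(
        order,
        [mappings[sid][2] for sid in order],
        [mappings[sid][3] for sid in order],
        [(mappings[sid][0], mappings[sid][1]) for sid in order],
    )
    return IterationResult(profiles, master, change_counts, unclassified, template)


def write_classification(
    master: CoreAlignment, unclassified: list[str], path
) -> None:
    """Tab-separated per-sequence classification report."""
    with open(path, "w") as fh:
        fh.write("seq_id\tprofile\tscore\tstatus\n")
        for i, sid in enumerate(master.ids):
            prof, score = master.provenance[i]
            fh.write(f"{sid}\t{prof}\t{score:.2f}\tclassified\n")
        for sid in unclassified:
            fh.write(f"{sid}\t-\t-\tunclassified\n")
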
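"""Bayesian partitioning with pattern selection over a subgroup hierarchy.

Given a master core alignment and a predefined hierarchy of subgroups,
the sampler jointly infers (i) each non-seed sequence's leaf-subgroup
assignment and (ii) for every non-root node a *pattern* — a small set of
core columns, each with a residue set drawn from a catalog of biochemical
classes — that discriminates the node's foreground (sequences assigned to
its subtree) from its background (the remaining sequences of the parent's
subtree).

The score of a pattern column is a log Bayes factor comparing two
beta-binomial models of the match counts: separate foreground and
background match rates versus a single shared rate, under Jeffreys
priors.  Columns where the foreground is not enriched are reported with
a non-positive value so that only foreground-enriched columns are
eligible pattern columns.  Pattern size is regularised by a geometric
prior contributing ``log(rho)`` per column.

Sampling alternates full Gibbs sweeps over non-seed sequence assignments
(proportional to the exponentiated change in total log-score) with
Metropolis moves on each node's pattern (add / remove / residue-set
change), under a linear temperature decay to greedy over the burn-in.
Sequence counts are redundancy-weighted ("virtual" counts); gaps count
as non-matches; seed sequences are never reassigned, and every pattern
residue set must contain the node's seed-consensus residue at that
column.
"""
from __future__ import annotations

import math
from copy import deepcopy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

from .alphabet import AA_INDEX, AMINO_ACIDS, catalog_sets_containing
from .core import CoreAlignment
from .profiles import consensus as _consensus
from .profiles import position_based_weights

JEFFREYS = (0.5, 0.5)
DEFAULT_RHO = 0.2


# ---------------------------------------------------------------------------
# Hierarchy specification
# ---------------------------------------------------------------------------
@dataclass
class HierarchyNode:
    name: str
    parent: str | None
    internal: bool = False
    seeds: frozenset = frozenset()


class HierarchySpec:
    """Tree of subgroup nodes with optional per-node seed sequences."""

    def __init__(self, nodes: list[HierarchyNode]):
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        self.nodes = {n.name: n for n in nodes}
        roots = [n.name for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError("hierarchy must have a single root")
        self.root = roots[0]
        for n in nodes:
            if n.parent is not None and n.parent not in self.nodes:
                raise ValueError(f"unknown parent {n.parent!r}")
        self.children: dict[str, list[str]] = {n.name: [] for n in nodes}
        for n in nodes:
            if n.parent is not None:
                self.children[n.parent].append(n.name)
        # acyclicity / reachability
        for name in names:
            self.ancestry(name)
        seen: dict[str, str] = {}
        for n in nodes:
            for s in n.seeds:
                if s in seen:
                    raise ValueError(f"seed {s!r} assigned to two nodes")
                seen[s] = n.name
        self.leaves = [n for n in names if not self.children[n]]

    def ancestry(self, name: str) -> list[str]:
        """Node and its ancestors up to (and including) the root."""
        chain, cur = [], name
        while cur is not None:
            chain.append(cur)
            cur = self.nodes[cur].parent
            if len(chain) > len(self.nodes):
                raise ValueError("cycle in hierarchy")
        return chain

    def subtree(self, name: str) -> list[str]:
        out, stack = [], [name]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.children[cur])
        return out

    def subtree_leaves(self, name: str) -> list[str]:
        return [n for n in self.subtree(name) if n in set(self.leaves)]

    # -- plain-text format -------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "HierarchySpec":
        """Indented hierarchy, one node per line.

        Two spaces per level; a trailing ``?`` marks an internal
        (higher-level) group; an optional second field lists seed
        sequence ids, comma-separated.
        """
        nodes: list[HierarchyNode] = []
        stack: list[tuple[int, str]] = []
        for raw in text.splitlines():
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            indent = len(raw) - len(raw.lstrip(" "))
            if indent % 2:
                raise ValueError(f"odd indentation: {raw!r}")
            depth = indent // 2
            fields = raw.split()
            name = fields[0]
            internal = name.endswith("?")
            if internal:
                name = name[:-1]
            seeds = frozenset(fields[1].split(",")) if len(fields) > 1 else frozenset()
            while stack and stack[-1][0] >= depth:
                stack.pop()
            parent = stack[-1][1] if stack else None
            nodes.append(HierarchyNode(name, parent, internal, seeds))
            stack.append((depth, name))
        return cls(nodes)

    @classmethod
    def read(cls, path) -> "HierarchySpec":
        from pathlib import Path

        return cls.parse(Path(path).read_text())

    @classmethod
    def flat(
        cls,
        groups: list[str],
        seeds: dict[str, list[str]] | None = None,
        root: str = "ELK",
    ) -> "HierarchySpec":
        """A single internal root with the given leaf groups."""
        seeds = seeds or {}
        nodes = [HierarchyNode(root, None, internal=True)]
        for g in groups:
            nodes.append(
                HierarchyNode(g, root, seeds=frozenset(seeds.get(g, ())))
            )
        return cls(nodes)


# ---------------------------------------------------------------------------
# Column contrast score
# ---------------------------------------------------------------------------
def _contrast_vec(fm, ft, bm, bt, alpha=JEFFREYS[0], beta=JEFFREYS[1]):
    """Vectorised signed log Bayes factor (see :func:`column_contrast`)."""
    fm = np.clip(np.asarray(fm, dtype=float), 0.0, None)
    bm = np.clip(np.asarray(bm, dtype=float), 0.0, None)
    fm = np.minimum(fm, ft)
    bm = np.minimum(bm, bt)
    lb0 = betaln(alpha, beta)
    m1 = (
        betaln(alpha + fm, beta + ft - fm)
        + betaln(alpha + bm, beta + bt - bm)
        - 2 * lb0
    )
    m0 = betaln(alpha + fm + bm, beta + (ft - fm) + (bt - bm)) - lb0
    raw = m1 - m0
    enriched = fm * bt > bm * ft
    return np.where(enriched, raw, -np.abs(raw))


def column_contrast(
    fg_match: float,
    fg_total: float,
    bg_match: float,
    bg_total: float,
    alpha: float = JEFFREYS[0],
    beta: float = JEFFREYS[1],
) -> float:
    """Signed log Bayes factor for separate vs shared match rates.

    Counts may be real-valued (weighted).  The two-rate beta-binomial
    evidence is compared against a single shared-rate model; when the
    foreground match rate does not exceed the background rate the
    magnitude is reported with a negative sign, so only
    foreground-enriched columns can improve a node score.
    """
    if fg_total <= 0 or bg_total <= 0:
        raise ValueError("foreground and background totals must be positive")
    if fg_match > fg_total + 1e-9 or bg_match > bg_total + 1e-9:
        raise ValueError("matches exceed totals")
    return float(
        _contrast_vec(
            np.array([fg_match]),
            float(fg_total),
            np.array([bg_match]),
            float(bg_total),
            alpha,
            beta,
        )[0]
    )


# ---------------------------------------------------------------------------
# Partition state
# ---------------------------------------------------------------------------
class PartitionState:
    """Current assignments + patterns, with incrementally maintained counts.

    For every non-root node ``u`` the state tracks, per pattern column,
    the weighted match count over the node's foreground (``fm``) and over
    its parent's subtree (``pm``); the background counts are the
    differences.  The invariant |foreground| + |background| =
    |subtree(parent)| holds by construction.
    """

    def __init__(
        self,
        master: CoreAlignment,
        spec: HierarchySpec,
        assignment: dict[str, str] | None = None,
        patterns: dict[str, dict[int, frozenset]] | None = None,
        weights: np.ndarray | None = None,
        rho: float = DEFAULT_RHO,
        rng: np.random.Generator | None = None,
    ):
        if len(spec.leaves) < 2:
            raise ValueError("hierarchy needs at least two leaf nodes")
        self.master = master
        self.spec = spec
        self.rho = rho
        self.iteration = 0
        n = len(master)
        L = master.core_length
        self.n, self.L = n, L
        self.w = (
            np.asarray(weights, dtype=float)
            if weights is not None
            else position_based_weights(master).weights
        )
        self.W = float(self.w.sum())
        # integer codes; gap/unknown -> 20
        self.codes = np.full((n, L), 20, dtype=np.int8)
        for i, row in enumerate(master.rows):
            for c, ch in enumerate(row):
                j = AA_INDEX.get(ch)
                if j is not None:
                    self.codes[i, c] = j

        self.leaves = list(spec.leaves)
        self.leaf_index = {g: k for k, g in enumerate(self.leaves)}
        self.snodes = [name for name in spec.nodes if name != spec.root]
        self.parent = {u: spec.nodes[u].parent for u in self.snodes}
        self._anc = {
            g: set(spec.ancestry(g)) - {spec.root} for g in self.leaves
        }

        # seed bookkeeping: seeds fix assignment to their (leaf) node
        self.seed_rows: dict[int, str] = {}
        for name, node in spec.nodes.items():
            if not node.seeds:
                continue
            if name not in self.leaf_index:
                raise ValueError(
                    f"seeds must attach to leaf nodes (node {name!r})"
                )
            for sid in node.seeds:
                self.seed_rows[master.row_index(sid)] = name

        # seed consensus per scoring node (over subtree seed rows)
        self.seed_consensus: dict[str, str | None] = {}
        for u in self.snodes:
            rows = [
                master.row_index(sid)
                for leaf in spec.subtree_leaves(u)
                for sid in spec.nodes[leaf].seeds
            ]
            self.seed_consensus[u] = (
                _consensus(master.subset(rows)) if rows else None
            )

        # initial assignment
        rng = rng or np.random.default_rng(0)
        self.assignment = np.empty(n, dtype=np.int64)
        if assignment is not None:
            for i, sid in enumerate(master.ids):
                self.assignment[i] = self.leaf_index[assignment[sid]]
        else:
            self.assignment[:] = rng.integers(0, len(self.leaves), size=n)
        for row, leaf in self.seed_rows.items():
            self.assignment[row] = self.leaf_index[leaf]

        self.patterns: dict[str, dict[int, frozenset]] = {
            u: dict((patterns or {}).get(u, {})) for u in self.snodes
        }
        self._match_cache: dict[tuple[int, frozenset], np.ndarray] = {}
        self._rebuild()

    # -- bookkeeping -------------------------------------------------------
    def _match_vec(self, col: int, rset: frozenset) -> np.ndarray:
        key = (col, rset)
        vec = self._match_cache.get(key)
        if vec is None:
            lut = np.zeros(21, dtype=bool)
            for r in rset:
                lut[AA_INDEX[r]] = True
            vec = lut[self.codes[:, col]]
            self._match_cache[key] = vec
        return vec

    def _membership(self, u: str, leaf: str) -> str:
        if u in self._anc[leaf]:
            return "fg"
        p = self.parent[u]
        if p == self.spec.root or p in self._anc[leaf]:
            return "bg"
        return "none"

    def _rebuild(self) -> None:
        """Recompute masks and counts from assignment + patterns."""
        self.fg_mask: dict[str, np.ndarray] = {}
        leaf_of = np.array(
            [self.leaves[k] for k in self.assignment], dtype=object
        )
        for u in self.snodes:
            under = set(self.spec.subtree_leaves(u))
            self.fg_mask[u] = np.fromiter(
                (g in under for g in leaf_of), dtype=bool, count=self.n
            )
        self._node: dict[str, dict] = {}
        for u in self.snodes:
            self._node[u] = {}
            self._set_node_cache(u)

    def _parent_mask(self, u: str) -> np.ndarray:
        p = self.parent[u]
        if p == self.spec.root:
            return np.ones(self.n, dtype=bool)
        return self.fg_mask[p]

    def _set_node_cache(self, u: str) -> None:
        cols = sorted(self.patterns[u].items())
        k = len(cols)
        M = np.zeros((k, self.n))
        for idx, (c, rset) in enumerate(cols):
            M[idx] = self.w * self._match_vec(c, rset)
        fg = self.fg_mask[u]
        pmask = self._parent_mask(u)
        self._node[u] = {
            "cols": cols,
            "M": M,
            "fm": M[:, fg].sum(axis=1),
            "pm": M[:, pmask].sum(axis=1),
            "ft": float(self.w[fg].sum()),
            "pt": float(self.w[pmask].sum()),
        }

    def _apply(self, s: int, leaf_idx: int, sign: int) -> None:
        leaf = self.leaves[leaf_idx]
        ws = sign * self.w[s]
        for u in self.snodes:
            mem = self._membership(u, leaf)
            if mem == "none":
                continue
            nd = self._node[u]
            mcol = sign * nd["M"][:, s]
            nd["pm"] += mcol
            nd["pt"] += ws
            if mem == "fg":
                nd["fm"] += mcol
                nd["ft"] += ws
                self.fg_mask[u][s] = sign > 0

    # -- scoring -----------------------------------------------------------
    def _score_counts(self, fm, ft, pm, pt, k: int) -> float:
        if k == 0:
            return 0.0
        bt = pt - ft
        if ft <= 1e-12 or bt <= 1e-12:
            return k * math.log(self.rho)
        bm = pm - fm
        return float(
            _contrast_vec(fm, ft, bm, bt).sum() + k * math.log(self.rho)
        )

    def node_score(self, u: str) -> float:
        if u == self.spec.root:
            raise ValueError("the root node has no foreground/background contrast")
        nd = self._node[u]
        return self._score_counts(
            nd["fm"], nd["ft"], nd["pm"], nd["pt"], len(nd["cols"])
        )

    def total_score(self) -> float:
        return sum(self.node_score(u) for u in self.snodes)

    def node_contrasts(self, u: str) -> list[tuple[int, frozenset, float, float, float]]:
        """Per pattern column: (col, residue set, fg rate, bg rate, contrast)."""
        nd = self._node[u]
        out = []
        bt = nd["pt"] - nd["ft"]
        for idx, (c, rset) in enumerate(nd["cols"]):
            fm, pm = nd["fm"][idx], nd["pm"][idx]
            bm = pm - fm
            fr = fm / nd["ft"] if nd["ft"] > 0 else 0.0
            br = bm / bt if bt > 0 else 0.0
            contrast = (
                column_contrast(fm, nd["ft"], max(bm, 0.0), bt)
                if nd["ft"] > 0 and bt > 0
                else 0.0
            )
            out.append((c, rset, fr, br, contrast))
        return out

    def foreground_indices(self, u: str) -> np.ndarray:
        return np.flatnonzero(self.fg_mask[u])

    def background_indices(self, u: str) -> np.ndarray:
        return np.flatnonzero(self._parent_mask(u) & ~self.fg_mask[u])

    def pattern_sizes(self) -> dict[str, int]:
        return {u: len(self.patterns[u]) for u in self.snodes}

    def assignment_labels(self) -> dict[str, str]:
        return {
            sid: self.leaves[self.assignment[i]]
            for i, sid in enumerate(self.master.ids)
        }

    def copy(self) -> "PartitionState":
        new = PartitionState.__new__(PartitionState)
        new.__dict__.update(self.__dict__)
        new.assignment = self.assignment.copy()
        new.patterns = deepcopy(self.patterns)
        new._match_cache = self._match_cache
        new._rebuild()
        return new

    # -- candidate evaluation -----------------------------------------------
    def _candidate_totals(self, s: int) -> np.ndarray:
        """Total log-score for assigning (removed) sequence ``s`` per leaf."""
        ws = self.w[s]
        sc = {}
        for u in self.snodes:
            nd = self._node[u]
            k = len(nd["cols"])
            mcol = nd["M"][:, s]
            sc[u] = (
                self._score_counts(nd["fm"], nd["ft"], nd["pm"], nd["pt"], k),
                self._score_counts(
                    nd["fm"], nd["ft"], nd["pm"] + mcol, nd["pt"] + ws, k
                ),
                self._score_counts(
                    nd["fm"] + mcol,
                    nd["ft"] + ws,
                    nd["pm"] + mcol,
                    nd["pt"] + ws,
                    k,
                ),
            )
        totals = np.empty(len(self.leaves))
        for li, leaf in enumerate(self.leaves):
            tot = 0.0
            for u in self.snodes:
                mem = self._membership(u, leaf)
                tot += sc[u][0 if mem == "none" else (2 if mem == "fg" else 1)]
            totals[li] = tot
        return totals

    def _column_counts(self, u: str, col: int, rset: frozenset) -> tuple:
        mvec = self.w * self._match_vec(col, rset)
        fg = self.fg_mask[u]
        pmask = self._parent_mask(u)
        return float(mvec[fg].sum()), float(mvec[pmask].sum())


def assignment_distribution(
    state: PartitionState, s: int, temperature: float = 1.0
) -> np.ndarray:
    """Gibbs proposal probabilities over leaves for sequence row ``s``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive for a distribution")
    old = state.assignment[s]
    state._apply(s, old, -1)
    totals = state._candidate_totals(s)
    state._apply(s, old, +1)
    z = (totals - totals.max()) / temperature
    p = np.exp(z)
    return p / p.sum()


def node_score(state: PartitionState, node: str) -> float:
    """Contrast sum minus complexity penalty for one non-root node."""
    return state.node_score(node)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------
def _metropolis(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    if delta > 0:
        return True
    if temperature <= 0:
        return False
    return rng.random() < math.exp(delta / temperature)


def _anchor_residue(state: PartitionState, u: str, col: int) -> str | None:
    """Residue anchoring candidate sets at a column (seed consensus)."""
    cons = state.seed_consensus[u]
    if cons is not None:
        r = cons[col]
        return r if r in AA_INDEX else None
    # no seeds under this node: anchor on the weighted foreground majority
    fg = state.fg_mask[u]
    if not fg.any():
        return None
    counts = np.bincount(
        state.codes[fg, col], weights=state.w[fg], minlength=21
    )[:20]
    if counts.sum() == 0:
        return None
    return AMINO_ACIDS[int(np.argmax(counts))]


def gibbs_sweep(
    state: PartitionState,
    rng: np.random.Generator,
    temperature: float = 0.0,
    max_pattern_size: int = 15,
) -> PartitionState:
    """One full sweep: resample assignments, then propose pattern moves.

    At zero temperature both phases are greedy (argmax assignment,
    accept-if-improving pattern moves) so the total log-score is
    non-decreasing.  Deterministic given the generator state.
    """
    log_rho = math.log(state.rho)
    # (a) sequence assignments
    nonseed = [i for i in range(state.n) if i not in state.seed_rows]
    for s in rng.permutation(np.array(nonseed, dtype=np.int64)):
        old = state.assignment[s]
        state._apply(s, old, -1)
        totals = state._candidate_totals(s)
        if temperature <= 0:
            new = int(np.argmax(totals))
        else:
            z = (totals - totals.max()) / temperature
            p = np.exp(z)
            new = int(rng.choice(len(p), p=p / p.sum()))
        state.assignment[s] = new
        state._apply(s, new, +1)

    # (b) pattern moves
    for u in state.snodes:
        nd = state._node[u]
        if nd["ft"] <= 0 or nd["pt"] - nd["ft"] <= 0:
            continue
        for c in rng.permutation(state.L):
            c = int(c)
            pattern = state.patterns[u]
            ft, pt = nd["ft"], nd["pt"]
            bt = pt - ft
            if c in pattern:
                idx = [k for k, (cc, _) in enumerate(nd["cols"]) if cc == c][0]
                fm, pm = nd["fm"][idx], nd["pm"][idx]
                cur = float(_contrast_vec(fm, ft, pm - fm, bt))
                # candidate 1: remove the column
                best_delta, best_action = -cur - log_rho, ("remove", None)
                # candidate 2: switch the residue set
                anchor = _anchor_residue(state, u, c)
                if anchor is not None:
                    for rset in catalog_sets_containing(anchor):
                        if rset == pattern[c]:
                            continue
                        fm2, pm2 = state._column_counts(u, c, rset)
                        d = float(_contrast_vec(fm2, ft, pm2 - fm2, bt)) - cur
                        if d > best_delta:
                            best_delta, best_action = d, ("change", rset)
                if _metropolis(best_delta, temperature, rng):
                    action, rset = best_action
                    if action == "remove":
                        del pattern[c]
                    else:
                        pattern[c] = rset
                    state._set_node_cache(u)
                    nd = state._node[u]
            else:
                if len(pattern) >= max_pattern_size:
                    continue
                anchor = _anchor_residue(state, u, c)
                if anchor is None:
                    continue
                best_delta, best_set = -math.inf, None
                for rset in catalog_sets_containing(anchor):
                    fm2, pm2 = state._column_counts(u, c, rset)
                    d = float(_contrast_vec(fm2, ft, pm2 - fm2, bt)) + log_rho
                    if d > best_delta:
                        best_delta, best_set = d, rset
                if best_set is not None and _metropolis(
                    best_delta, temperature, rng
                ):
                    pattern[c] = best_set
                    state._set_node_cache(u)
                    nd = state._node[u]
    state.iteration += 1
    return state


def run_mcbpps(
    master: CoreAlignment,
    spec: HierarchySpec,
    n_sweeps: int = 60,
    burn_in: int = 30,
    rng_seed: int = 0,
    rho: float = DEFAULT_RHO,
    t0: float = 1.0,
    max_pattern_size: int = 15,
    init_pattern_size: int = 2,
    weights: np.ndarray | None = None,
    n_chains: int = 3,
) -> tuple[PartitionState, list[dict]]:
    """Run the sampler and return a consensus-pruned best state.

    ``n_chains`` independent chains are run from different random
    initialisations (seeds derived from ``rng_seed``).  The best-scoring
    chain provides the assignments, and its pattern columns are pruned
    to those recovered by *every* chain: genuinely discriminating
    columns are stable attractors that all chains reach, whereas columns
    manufactured by co-adapting assignments to sampling noise differ
    from chain to chain.  With ``n_chains=1`` the single chain's state
    is returned unpruned.
    """
    for name, node in spec.nodes.items():
        for sid in node.seeds:
            if sid not in master._index:
                raise ValueError(f"seed {sid!r} missing from master alignment")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_chains > 1:
        states = [
            _run_single_chain(
                master,
                spec,
                n_sweeps,
                burn_in,
                int((rng_seed + 1000003 * k) % (2**31 - 1)),
                rho,
                t0,
                max_pattern_size,
                init_pattern_size,
                weights,
            )
            for k in range(n_chains)
        ]
        best = max(states, key=lambda s: s.total_score())
        for u in best.snodes:
            keep = set(best.patterns[u])
            for other in states:
                keep &= set(other.patterns[u])
            best.patterns[u] = {
                c: best.patterns[u][c] for c in sorted(keep)
            }
        best._rebuild()
        return best, build_report(best)
    state = _run_single_chain(
        master,
        spec,
        n_sweeps,
        burn_in,
        rng_seed,
        rho,
        t0,
        max_pattern_size,
        init_pattern_size,
        weights,
    )
    return state, build_report(state)


def _run_single_chain(
    master: CoreAlignment,
    spec: HierarchySpec,
    n_sweeps: int,
    burn_in: int,
    rng_seed: int,
    rho: float,
    t0: float,
    max_pattern_size: int,
    init_pattern_size: int,
    weights: np.ndarray | None,
) -> PartitionState:
    """One annealed chain; returns the best state visited after burn-in."""
    rng = np.random.default_rng(rng_seed)
    state = PartitionState(
        master, spec, weights=weights, rho=rho, rng=rng
    )
    # random initial patterns
    for u in state.snodes:
        eligible = [
            c
            for c in range(state.L)
            if _anchor_residue(state, u, c) is not None
        ]
        if not eligible:
            continue
        for c in rng.choice(
            eligible, size=min(init_pattern_size, len(eligible)), replace=False
        ):
            anchor = _anchor_residue(state, u, int(c))
            sets = catalog_sets_containing(anchor)
            state.patterns[u][int(c)] = sets[int(rng.integers(len(sets)))]
        state._set_node_cache(u)

    best: tuple[float, np.ndarray, dict] | None = None
    for t in range(n_sweeps):
        temperature = (
            t0 * max(0.0, 1.0 - t / burn_in) if burn_in > 0 else 0.0
        )
        gibbs_sweep(state, rng, temperature, max_pattern_size)
        if t >= burn_in:
            sc = state.total_score()
            if best is None or sc > best[0]:
                best = (sc, state.assignment.copy(), deepcopy(state.patterns))
    if best is not None:
        state.assignment = best[1]
        state.patterns = best[2]
        state._rebuild()
    return state


def build_report(state: PartitionState) -> list[dict]:
    """Per-node pattern columns sorted by contrast (1-based columns)."""
    rows = []
    for u in state.snodes:
        ranked = sorted(
            state.node_contrasts(u), key=lambda r: -r[4]
        )
        for rank, (c, rset, fr, br, contrast) in enumerate(ranked, start=1):
            rows.append(
                {
                    "node": u,
                    "rank": rank,
                    "column": c + 1,
                    "residues": "".join(sorted(rset)),
                    "fg_match_pct": 100.0 * fr,
                    "bg_match_pct": 100.0 * br,
                    "log_contrast": contrast,
                }
            )
    return rows


def write_report(report: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "node\trank\tcolumn\tresidue_set\tfg_match_pct\tbg_match_pct\tlog_contrast\n"
        )
        for r in report:
            fh.write(
                f"{r['node']}\t{r['rank']}\t{r['column']}\t{r['residues']}\t"
                f"{r['fg_match_pct']:.1f}\t{r['bg_match_pct']:.1f}\t"
                f"{r['log_contrast']:.3f}\n"
            )
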
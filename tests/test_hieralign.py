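"""Profile alignment DP, core mapping and the iterative refinement loop."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from elkin.core import CoreAlignment, SequenceRecord
from elkin.hieralign import (
    TemplateAlignment,
    align_and_map,
    align_to_profile,
    best_profile,
    iterate_profiles,
    map_to_core,
    template_from_groups,
    _score_matrix,
)
from elkin.profiles import build_profile, position_based_weights
from elkin.synthetic import SuperfamilyConfig, generate_superfamily

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_best(S, go, ge, mode="local"):
    """Exhaustive maximum over all monotone matchings with affine gaps.

    Enumerates every ordered pairing of sequence positions with profile
    columns; a gap run of length g costs go + ge*g.  In local mode the
    flanks are free and the empty alignment scores 0; in semiglobal mode
    unmatched profile columns at either end are charged as deletions.
    """
    m, L = S.shape
    if mode == "local":
        best = 0.0
    else:
        best = -(go + ge * L)  # all columns deleted
    for k in range(1, min(m, L) + 1):
        for si in itertools.combinations(range(m), k):
            for pj in itertools.combinations(range(L), k):
                sc = sum(S[i, j] for i, j in zip(si, pj))
                for t in range(1, k):
                    gi = si[t] - si[t - 1] - 1
                    gj = pj[t] - pj[t - 1] - 1
                    if gi:
                        sc -= go + ge * gi
                    if gj:
                        sc -= go + ge * gj
                if mode == "semiglobal":
                    lead, trail = pj[0], L - pj[-1] - 1
                    if lead:
                        sc -= go + ge * lead
                    if trail:
                        sc -= go + ge * trail
                best = max(best, sc)
    return best


def random_profile(rng, L):
    rows = ["".join(rng.choice(list(AA), L)) for _ in range(3)]
    a = CoreAlignment([f"s{i}" for i in range(3)], rows)
    return build_profile(a, pseudocount_strength=2.0, name="p")


@pytest.mark.parametrize("mode", ["local", "semiglobal"])
def test_dp_equals_brute_force_on_small_instances(mode):
    """Affine-gap DP scores match exhaustive enumeration for all
    sequence/profile sizes up to 8."""
    rng = np.random.default_rng(101)
    for _ in range(60):
        L = int(rng.integers(1, 9))
        m = int(rng.integers(1, 9))
        p = random_profile(rng, L)
        seq = "".join(rng.choice(list(AA), m))
        got = align_to_profile(seq, p, mode=mode).score
        want = brute_force_best(
            _score_matrix(seq, p), p.gap_open, p.gap_extend, mode
        )
        assert got == pytest.approx(want, abs=1e-9)


def test_consensus_aligns_gap_free_with_maximal_score():
    rng = np.random.default_rng(5)
    p = random_profile(rng, 12)
    a = align_to_profile(p.consensus, p, mode="local")
    assert a.pairs == [(i, i) for i in range(12)]
    # no other sequence of the same length scores higher
    for _ in range(20):
        other = "".join(rng.choice(list(AA), 12))
        assert align_to_profile(other, p).score <= a.score + 1e-9


def test_shuffled_sequences_fall_below_significance(small_superfamily):
    records, master, truth = small_superfamily
    g0 = [i for i, sid in enumerate(master.ids) if truth.labels[sid] == "G0"]
    sub = master.subset(g0)
    prof = build_profile(sub, weights=position_based_weights(sub), name="G0")
    rng = np.random.default_rng(77)
    seq = list(records[0].seq)
    below = 0
    for _ in range(100):
        rng.shuffle(seq)
        if align_to_profile("".join(seq), prof).score < 25.0:
            below += 1
    assert below >= 95


def test_best_profile_contract(small_superfamily):
    records, master, truth = small_superfamily
    groups = {}
    for i, sid in enumerate(master.ids):
        groups.setdefault(truth.labels[sid], []).append(i)
    profs = {
        g: build_profile(
            master.subset(ix),
            weights=position_based_weights(master.subset(ix)),
            name=g,
        )
        for g, ix in groups.items()
    }
    # single profile: that profile wins
    name, _, _ = best_profile(records[0], {"G0": profs["G0"]}, threshold=0.0)
    assert name == "G0"
    # random sequence: unclassified status, not an exception
    rng = np.random.default_rng(3)
    junk = SequenceRecord("junk", "".join(rng.choice(list(AA), 120)))
    name, score, aln = best_profile(junk, profs)
    assert name is None and aln is None
    with pytest.raises(ValueError):
        best_profile(records[0], {})


def test_true_group_recovery_rate(small_superfamily):
    """Nearly every sequence is assigned its true group's profile."""
    records, master, truth = small_superfamily
    groups = {}
    for i, sid in enumerate(master.ids):
        groups.setdefault(truth.labels[sid], []).append(i)
    seed_alns = {g: master.subset(ix) for g, ix in sorted(groups.items())}
    profs = {
        g: build_profile(a, weights=position_based_weights(a), name=g)
        for g, a in seed_alns.items()
    }
    template = template_from_groups(seed_alns)
    correct = 0
    for rec in records:
        name, _, _, _ = align_and_map(rec, profs, template)
        correct += name == truth.labels[rec.id]
    assert correct / len(records) >= 0.98


class TestMapToCore:
    def test_root_consensus_identity_mapping(self):
        rng = np.random.default_rng(1)
        p = random_profile(rng, 10)
        template = TemplateAlignment(
            {"p": p.consensus}, {"p": None}
        )
        a = align_to_profile(p.consensus, p, mode="semiglobal")
        row, inserts = map_to_core(a, template, p.consensus)
        assert row == p.consensus and inserts == {}

    def test_insert_attaches_to_preceding_core_column(self):
        """A 7-residue insert after core column 31 (1-based) lands at key
        30 with the core row unchanged, when the insert boundaries are
        flanked by invariant columns."""
        from elkin.synthetic import DEFAULT_CATALYTIC

        cfg = SuperfamilyConfig(
            rng_seed=8,
            seqs_per_group=20,
            insert_points=((30, 7, 7),),
            catalytic_columns=DEFAULT_CATALYTIC
            + ((29, "W"), (30, "C"), (31, "M"), (32, "H")),
        )
        records, aln, truth = generate_superfamily(cfg)
        groups = {}
        for i, sid in enumerate(aln.ids):
            groups.setdefault(truth.labels[sid], []).append(i)
        seed_alns = {g: aln.subset(ix) for g, ix in groups.items()}
        profs = {
            g: build_profile(a, weights=position_based_weights(a), name=g)
            for g, a in seed_alns.items()
        }
        template = template_from_groups(seed_alns)
        for i, rec in enumerate(records):
            _, _, row, inserts = align_and_map(rec, profs, template)
            assert set(inserts) == {30} and len(inserts[30]) == 7
            assert row == aln.rows[i]

    def test_template_gap_columns_become_inserts(self):
        """Profile columns absent from the root map become inserts."""
        rng = np.random.default_rng(2)
        p = random_profile(rng, 6)
        # root covers display cols 0..3 and 6..7; profile occupies 0..5
        template = TemplateAlignment(
            {"root": "ACDE--FG", "p": p.consensus + "--"},
            {"root": None, "p": "root"},
        )
        a = align_to_profile(p.consensus, p, mode="semiglobal")
        row, inserts = map_to_core(a, template, p.consensus)
        assert row == p.consensus[:4] + "--"
        assert inserts == {3: p.consensus[4:6]}

    def test_round_trip_reconstruction_for_generated_data(
        self, small_superfamily
    ):
        records, master, truth = small_superfamily
        groups = {}
        for i, sid in enumerate(master.ids):
            groups.setdefault(truth.labels[sid], []).append(i)
        seed_alns = {g: master.subset(ix) for g, ix in groups.items()}
        profs = {
            g: build_profile(a, weights=position_based_weights(a), name=g)
            for g, a in seed_alns.items()
        }
        template = template_from_groups(seed_alns)
        for rec in records:
            _, _, row, inserts = align_and_map(rec, profs, template)
            rebuilt = CoreAlignment([rec.id], [row], [inserts])
            assert rebuilt.reconstruct(0) == rec.seq


@given(seed=st.integers(0, 10_000))
def test_exact_core_recovery_without_inserts(seed):
    """generate -> degap -> realign with the true profiles recovers the
    planted core columns exactly when there are no inserts."""
    cfg = SuperfamilyConfig(
        rng_seed=seed, n_groups=2, hierarchy=(None, None),
        seqs_per_group=6, insert_points=(),
    )
    records, aln, truth = generate_superfamily(cfg)
    groups = {}
    for i, sid in enumerate(aln.ids):
        groups.setdefault(truth.labels[sid], []).append(i)
    seed_alns = {g: aln.subset(ix) for g, ix in groups.items()}
    profs = {
        g: build_profile(a, weights=position_based_weights(a), name=g)
        for g, a in seed_alns.items()
    }
    template = template_from_groups(seed_alns)
    for i, rec in enumerate(records):
        _, _, row, inserts = align_and_map(rec, profs, template)
        assert row == aln.rows[i]
        assert not inserts


class TestIterateProfiles:
    def _setup(self, cfg):
        records, aln, truth = generate_superfamily(cfg)
        groups = {}
        for i, sid in enumerate(aln.ids):
            groups.setdefault(truth.labels[sid], []).append(i)
        return records, aln, truth, groups

    def test_fixed_point_when_data_matches_profiles(self):
        cfg = SuperfamilyConfig(rng_seed=4, seqs_per_group=15, insert_points=())
        records, aln, truth, groups = self._setup(cfg)
        seed_alns = {g: aln.subset(ix) for g, ix in groups.items()}
        res = iterate_profiles(seed_alns, records, n_rounds=2)
        assert res.change_counts[1] == 0

    def test_changes_do_not_increase_between_rounds(self, small_superfamily):
        records, master, truth = small_superfamily
        groups = {}
        for i, sid in enumerate(master.ids):
            groups.setdefault(truth.labels[sid], []).append(i)
        seed_alns = {g: master.subset(ix[:10]) for g, ix in groups.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = iterate_profiles(seed_alns, records, n_rounds=2)
        assert res.change_counts[1] <= res.change_counts[0]

    def test_zero_rounds_rejected(self, small_superfamily):
        records, master, truth = small_superfamily
        with pytest.raises(ValueError):
            iterate_profiles({}, records, n_rounds=0)
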
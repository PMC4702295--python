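import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elkin.bpps import HierarchySpec, PartitionState
from elkin.core import CoreAlignment
from elkin.synthetic import SuperfamilyConfig, generate_superfamily

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def small_superfamily():
    """4 flat groups x 40 sequences, 5 planted columns each, fg .95 / bg .05."""
    cfg = SuperfamilyConfig(rng_seed=11, seqs_per_group=40)
    return generate_superfamily(cfg)


@pytest.fixture(scope="session")
def flat_spec(small_superfamily):
    _, master, truth = small_superfamily
    groups = sorted(set(truth.labels.values()))
    seeds = {
        g: [s for s, l in truth.labels.items() if l == g][:3] for g in groups
    }
    return HierarchySpec.flat(groups, seeds)


@pytest.fixture(scope="session")
def truth_state(small_superfamily, flat_spec):
    """Partition state pinned at the generator truth (assignment + patterns)."""
    _, master, truth = small_superfamily
    patterns = {
        g: {c: frozenset(r) for c, r in truth.patterns[g].items()}
        for g in sorted(set(truth.labels.values()))
    }
    return PartitionState(
        master, flat_spec, assignment=truth.labels, patterns=patterns
    )


def make_identity_families(
    n_families=3,
    members=20,
    length=100,
    intra_mut=0.10,
    inter_mut=0.70,
    seed=0,
):
    """Aligned families at ~(1-intra_mut)^2 within / ~(1-inter_mut) between.

    Family centers are successive mutants of one ancestor (``inter_mut``
    of columns changed); members mutate ``intra_mut`` of columns.
    """
    rng = np.random.default_rng(seed)

    def mutate(s, frac):
        s = list(s)
        k = int(round(frac * len(s)))
        for i in rng.choice(len(s), size=k, replace=False):
            s[i] = AA[(AA.index(s[i]) + 1 + int(rng.integers(19))) % 20]
        return "".join(s)

    ancestor = "".join(rng.choice(list(AA), size=length))
    centers = [mutate(ancestor, inter_mut) for _ in range(n_families)]
    ids, rows, labels = [], [], {}
    for f, center in enumerate(centers):
        for m in range(members):
            sid = f"F{f}_m{m:02d}"
            ids.append(sid)
            rows.append(mutate(center, intra_mut))
            labels[sid] = f
    return CoreAlignment(ids, rows), labels
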
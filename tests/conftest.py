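import numpy as np
import pytest

from raresyn import synth
from raresyn.io_core import Alignment, GroupDefinition, ReferenceDB, tree_from_string


@pytest.fixture
def quartet_tree():
    return tree_from_string("((A:0.3,B:0.5):0.4,(C:0.2,D:0.7):0.1);")


@pytest.fixture
def quartet_alignment():
    return Alignment("g", ["A", "B", "C", "D"], ["LV-W", "VVXW", "VWLW", "LWLW"])


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale study conditions: same planted structure, fewer species."""
    return synth.SimConfig(
        seed=11,
        n_group=60,
        n_outside=400,
        n_query=3,
        r_true=10.0,
        genes=(("atp6", 60), ("cytb", 60)),
        planted=(
            synth.PlantedFeature("atp6", 10, "S", "W", 0.95, 0.01, True),
            synth.PlantedFeature("atp6", 40, "L", "F", 0.90, 0.005, False),
            synth.PlantedFeature("cytb", 20, "F", "W", 0.92, 0.002, True),
        ),
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return synth.simulate_dataset(small_sim_config)


def make_exact_freq_db(
    s_counts, h_counts, n_group=100, n_outside=1000, derived="W", ancestral="S",
    query_carries=(),
):
    """Reference database where feature i's within-group and outside-group
    fractions are exactly s_counts[i]/n_group and h_counts[i]/n_outside.

    One gene 'g' with one column per feature. Query species carry the
    derived residue at the columns listed in query_carries.
    """
    n_feat = len(s_counts)
    group = [f"G{i:03d}" for i in range(n_group)]
    outside = [f"O{i:04d}" for i in range(n_outside)]
    queries = ["Q00", "Q01", "Q02"]
    rows = {}
    for k, sp in enumerate(group):
        rows[sp] = "".join(derived if k < s_counts[j] else ancestral for j in range(n_feat))
    for k, sp in enumerate(outside):
        rows[sp] = "".join(derived if k < h_counts[j] else ancestral for j in range(n_feat))
    for sp in queries:
        rows[sp] = "".join(derived if j in query_carries else ancestral for j in range(n_feat))
    taxonomy = {sp: ("Metazoa", "GroupA", sp) for sp in group}
    taxonomy.update({sp: ("Metazoa", "Outside", sp) for sp in outside})
    taxonomy.update({sp: ("Metazoa", "QueryQ", sp) for sp in queries})
    db = ReferenceDB(taxonomy=taxonomy, genes={"g": rows})
    gdef = GroupDefinition(
        name="GroupA", members=frozenset(group), query_set=frozenset(queries), query_min=2
    )
    return db, gdef


@pytest.fixture
def table_like_db():
    """Database realizing the canonical nine-feature screening example:
    within-group percentages (83, 87, 63, 83, 81, 97, 92, 94, 99) and
    outside percentages (0.6, 0.7, 3.0, 3.0, 1.3, 1.4, 2.7, 0.1, 1.1),
    with the query clade carrying features 2, 4, 8, 9 (1-based)."""
    s_counts = [83, 87, 63, 83, 81, 97, 92, 94, 99]
    h_counts = [6, 7, 30, 30, 13, 14, 27, 1, 11]
    return make_exact_freq_db(s_counts, h_counts, query_carries={1, 3, 7, 8})


def subset_enumeration_pb(h):
    """Independent Poisson-binomial oracle: explicit enumeration over all
    2^n emergence subsets."""
    h = np.asarray(h, dtype=float)
    prod = np.array([1.0])
    cnt = np.array([0])
    for hi in h:
        prod = np.concatenate([prod * (1.0 - hi), prod * hi])
        cnt = np.concatenate([cnt, cnt + 1])
    return np.bincount(cnt, weights=prod, minlength=len(h) + 1)
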
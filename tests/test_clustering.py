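import numpy as np
import pytest

from selectisom.clustering import (
    ClusterTable,
    composition,
    compositions_for_table,
    extract_clusters,
    performance,
    pure_cluster_report,
    round_half_up,
)
from selectisom.esom import SelfOrganizingMap
from selectisom.selectivity import SetLabel

KS, NS, SK = SetLabel.K_OVER_S, SetLabel.KS_NONSELECTIVE, SetLabel.S_OVER_K


def make_labels(counts_by_label):
    """{label: n} -> (member ids, {id: label})"""
    members, labels = [], {}
    i = 0
    for label, n in counts_by_label.items():
        for _ in range(n):
            cid = f"m{i}"
            members.append(cid)
            labels[cid] = label
            i += 1
    return members, labels


@pytest.mark.parametrize(
    "counts, expected_purity",
    [({KS: 2, NS: 15, SK: 10}, 56), ({KS: 28, NS: 2}, 93), ({SK: 4}, 100)],
)
def test_composition_purity_rounding(counts, expected_purity):
    members, labels = make_labels(counts)
    comp = composition(1, members, labels)
    assert comp.purity_pct == expected_purity
    assert comp.total == sum(counts.values())


def test_half_up_rounding_convention():
    assert round_half_up(55.5) == 56
    assert round_half_up(92.4999) == 92
    assert round_half_up(50.0) == 50


def test_decoys_excluded_from_purity_but_break_pureness():
    members, labels = make_labels({KS: 3})
    members += ["z1", "z2"]
    comp = composition(2, members, labels, {"z1": True, "z2": True})
    assert comp.purity_pct == 100
    assert comp.decoy_count == 2
    assert comp.total == 5
    assert not comp.is_pure_selectivity
    clean = composition(3, members[:3], labels)
    assert clean.is_pure_selectivity


def test_unlabeled_member_raises():
    with pytest.raises(KeyError):
        composition(1, ["mystery"], {})


def test_performance_identity_and_bounds(rng):
    """Exact coverage always equals exact correct + exact error."""
    for _ in range(30):
        comps = []
        total = 0
        for cid in range(rng.integers(1, 8)):
            counts = {lab: int(rng.integers(0, 6)) for lab in (KS, NS, SK)}
            if sum(counts.values()) == 0:
                counts[KS] = 1
            members, labels = make_labels(counts)
            members = [f"c{cid}_{m}" for m in members]
            labels = {f"c{cid}_{k}": v for k, v in labels.items()}
            comps.append(composition(cid, members, labels))
            total += sum(counts.values())
        n_library = total + int(rng.integers(0, 10))
        perf = performance(comps, n_library)
        assert perf.coverage_exact == pytest.approx(perf.correct_exact + perf.error_exact)
        assert 0 <= perf.error_exact <= perf.coverage_exact <= 100


def test_performance_single_pure_cluster_is_perfect():
    members, labels = make_labels({SK: 12})
    perf = performance([composition(1, members, labels)], 12)
    assert (perf.coverage_pct, perf.correct_pct, perf.error_pct) == (100, 100, 0)
    with pytest.raises(ValueError):
        performance([], 0)


def test_pure_cluster_report_filters_and_tallies():
    m1, l1 = make_labels({KS: 4})
    m2, l2 = make_labels({NS: 2, SK: 1})
    m3, l3 = make_labels({SK: 3})
    comps = [
        composition(1, m1, l1),
        composition(2, m2, l2),
        composition(3, m3, l3),
        composition(4, [f"d{i}" for i in range(2)] + m1[:1], l1, {"d0": True, "d1": True}),
    ]
    report = pure_cluster_report(comps)
    assert report["n_pure"] == 2
    assert report["pure_per_set"] == {"K/S": 1, "KS": 0, "S/K": 1}
    assert pure_cluster_report([])["n_pure"] == 0


@pytest.fixture
def toy_model():
    model = SelfOrganizingMap(rows=4, cols=5, epochs=1, random_state=0)
    model.fit(np.zeros((2, 3)))
    return model


def test_extract_clusters_theta_one_merges_adjacent(toy_model):
    umat = np.zeros((4, 5))
    projection = {"a": (0, 0), "b": (0, 1), "c": (1, 1)}
    table = extract_clusters(toy_model, projection, umat, theta=1.0)
    assert len(table.clusters) == 1
    assert sorted(table.clusters[1]) == ["a", "b", "c"]
    assert table.unclustered == []


def test_extract_clusters_ridge_separates_and_strands(toy_model):
    umat = np.zeros((4, 5))
    umat[1, :] = 0.9  # a ridge row
    umat[3, 3] = 0.95
    projection = {"a": (0, 0), "b": (0, 1), "ridge": (1, 0), "lone": (2, 3), "high": (3, 3)}
    table = extract_clusters(toy_model, projection, umat, theta=0.5)
    # toroidal wrap: row 0 and row 3 are adjacent, but (2,3)'s neighbors are empty
    members = {frozenset(m) for m in table.clusters.values()}
    assert frozenset({"a", "b"}) in members
    assert frozenset({"lone"}) in members  # singleton cluster on a low-U neuron
    assert set(table.unclustered) == {"ridge", "high"}
    # partition property
    assert sorted(table.all_members()) == sorted(projection)


def test_extract_clusters_wraps_around_torus(toy_model):
    umat = np.zeros((4, 5))
    projection = {"left": (2, 0), "right": (2, 4)}  # adjacent through the seam
    table = extract_clusters(toy_model, projection, umat, theta=0.5)
    assert len(table.clusters) == 1


def test_extract_clusters_validates_input(toy_model):
    with pytest.raises(ValueError):
        extract_clusters(toy_model, {}, np.zeros((4, 5)), 0.5)
    with pytest.raises(ValueError):
        extract_clusters(toy_model, {"a": (0, 0)}, np.zeros((4, 5)), 1.5)


def test_compositions_for_table_covers_all_clusters(toy_model):
    members, labels = make_labels({KS: 2, SK: 1})
    table = ClusterTable(clusters={1: members[:2], 2: members[2:]})
    comps = compositions_for_table(table, labels)
    assert [c.cluster_id for c in comps] == [1, 2]
    assert comps[0].purity_pct == 100
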
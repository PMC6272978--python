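import numpy as np
import pytest

from selectisom.esom import SelfOrganizingMap, _cross_distances, stratified_split


def small_model(**kw):
    params = dict(rows=4, cols=5, epochs=10, random_state=0)
    params.update(kw)
    return SelfOrganizingMap(**params)


def test_single_repeated_input_converges_to_fixed_point():
    x = np.array([[0.2, 0.8, 0.0, 1.0]])
    model = small_model(epochs=300).fit(np.repeat(x, 5, axis=0))
    assert model.quantization_error_trace_[-1] < 1e-6
    bmu = model.predict(x)[0]
    np.testing.assert_allclose(model.weights_[bmu], x[0], atol=1e-6)


def test_quantization_error_decreases(rng):
    X = rng.random((40, 8))
    model = small_model(rows=6, cols=6, epochs=20).fit(X)
    trace = model.quantization_error_trace_
    assert len(trace) == 21
    assert trace[-1] < trace[0]


@pytest.mark.parametrize("distance", ["euclidean", "tanimoto_dissimilarity"])
def test_bmu_matches_brute_force_argmin(rng, distance):
    for _ in range(50):
        model = small_model(distance=distance, epochs=2)
        X = rng.random((6, 7))
        model.fit(X)
        x = rng.random(7)
        if distance == "euclidean":
            dists = np.linalg.norm(model.weights_ - x, axis=1)
        else:
            dot = model.weights_ @ x
            dists = 1 - dot / (x @ x + (model.weights_ ** 2).sum(1) - dot)
        assert model.predict(x[None, :])[0] == int(np.argmin(dists))


def test_bmu_tie_breaks_to_lowest_row_col():
    model = small_model(epochs=1)
    model.fit(np.ones((3, 2)))
    model.weights_ = np.ones_like(model.weights_)  # force an all-way tie
    assert model.bmu(np.array([0.5, 0.5])) == (0, 0)


def test_umatrix_two_by_two_toroidal_hand_computation():
    """On a 2x2 torus every neuron's Moore neighborhood is the other three."""
    model = SelfOrganizingMap(rows=2, cols=2, epochs=1, random_state=0)
    model.fit(np.zeros((2, 1)))
    model.weights_ = np.array([[0.0], [1.0], [2.0], [4.0]])
    # raw sums: |0-1|+|0-2|+|0-4|=7, |1-0|+|1-2|+|1-4|=5,
    #           |2-0|+|2-1|+|2-4|=5, |4-0|+|4-1|+|4-2|=9 -> /9
    expected = np.array([[7.0, 5.0], [5.0, 9.0]]) / 9.0
    np.testing.assert_allclose(model.umatrix(), expected)


def test_umatrix_flat_map_is_zero_and_peak_is_one(rng):
    model = small_model(epochs=2)
    model.fit(rng.random((10, 3)))
    model.weights_ = np.full_like(model.weights_, 0.7)
    assert model.umatrix().max() == 0.0
    model.weights_ = rng.random(model.weights_.shape)
    assert model.umatrix().max() == pytest.approx(1.0)


def test_pmatrix_matches_double_loop(rng):
    model = small_model(epochs=3)
    X = rng.random((25, 7))
    model.fit(X)
    radius = 0.6
    pm = model.pmatrix(X, pareto_radius=radius)
    brute = np.zeros(model.rows * model.cols, dtype=int)
    for j, w in enumerate(model.weights_):
        for x in X:
            if np.linalg.norm(x - w) <= radius:
                brute[j] += 1
    np.testing.assert_array_equal(pm.reshape(-1), brute)
    with pytest.raises(ValueError):
        model.pmatrix(X, pareto_radius=-1.0)


def test_pmatrix_limit_cases(rng):
    model = small_model(epochs=2)
    X = rng.random((10, 4))
    model.fit(X)
    target = model.weights_[7]
    data = np.repeat(target[None, :], 6, axis=0)
    pm = model.pmatrix(data, pareto_radius=1e-6)
    assert pm.reshape(-1)[7] == 6
    tiny = model.pmatrix(X + 100.0, pareto_radius=1e-12)
    assert tiny.sum() == 0


def test_projection_is_pure_lookup_and_deterministic(rng):
    X = rng.random((20, 5))
    model = small_model(epochs=5).fit(X)
    weights_before = model.weights_.copy()
    first = model.project(X)
    second = model.project(X)
    np.testing.assert_array_equal(first, second)
    np.testing.assert_array_equal(model.weights_, weights_before)
    # training-time labels equal a fresh projection after the final epoch
    np.testing.assert_array_equal(model.labels_, model.predict(X))
    assert model.project(np.zeros((0, 5))).shape == (0, 2)


def test_identical_seed_gives_bit_identical_weights(rng):
    X = rng.random((15, 6))
    a = small_model(random_state=99).fit(X)
    b = small_model(random_state=99).fit(X)
    np.testing.assert_array_equal(a.weights_, b.weights_)
    c = small_model(random_state=100).fit(X)
    assert not np.array_equal(a.weights_, c.weights_)


def test_two_separated_clouds_occupy_disjoint_regions(rng):
    lo = rng.random((15, 20)) * 0.05
    hi = rng.random((15, 20)) * 0.05 + 1.0
    X = np.vstack([lo, hi])
    model = SelfOrganizingMap(rows=8, cols=10, epochs=30, random_state=3).fit(X)
    bmus = model.predict(X)
    assert set(bmus[:15]).isdisjoint(set(bmus[15:]))
    # neighborhood preservation: intra-cloud grid distance < inter-cloud
    coords = model.project(X).astype(float)

    def torus_dist(a, b):
        dr = np.abs(a[0] - b[0]); dc = np.abs(a[1] - b[1])
        return np.hypot(min(dr, 8 - dr), min(dc, 10 - dc))

    intra = [torus_dist(coords[i], coords[j]) for i in range(15) for j in range(i + 1, 15)]
    inter = [torus_dist(coords[i], coords[j]) for i in range(15) for j in range(15, 30)]
    assert np.mean(intra) < np.mean(inter)


def test_toroidal_shift_leaves_structure_invariant(rng):
    X = rng.random((12, 4))
    model = small_model(epochs=5).fit(X)
    umat = model.umatrix()
    shifted = small_model(epochs=5)
    shifted.fit(X)  # same seed: identical weights
    grid = shifted.weights_.reshape(shifted.rows, shifted.cols, -1)
    dr, dc = 2, 3
    shifted.weights_ = np.roll(grid, (dr, dc), axis=(0, 1)).reshape(-1, 4)
    np.testing.assert_allclose(
        shifted.umatrix(), np.roll(umat, (dr, dc), axis=(0, 1)), atol=1e-12
    )
    base = model.project(X)
    moved = shifted.project(X)
    np.testing.assert_array_equal(
        (base + [dr, dc]) % [model.rows, model.cols], moved
    )


def test_input_validation():
    model = small_model(epochs=1).fit(np.zeros((3, 4)))
    with pytest.raises(ValueError):
        model.predict(np.zeros((2, 5)))
    with pytest.raises(ValueError):
        SelfOrganizingMap(rows=2, cols=2, lr_start=0.1, lr_end=0.5).fit(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        SelfOrganizingMap(rows=2, cols=2, distance="manhattan").fit(np.zeros((2, 2)))


def test_bounded_topology_has_no_wraparound_neighbors():
    model = SelfOrganizingMap(rows=3, cols=4, topology="bounded", epochs=1)
    model.fit(np.zeros((2, 2)))
    assert model.neighbor_indices(0) == sorted({1, 4, 5})
    toroid = small_model(rows=3, cols=4, epochs=1).fit(np.zeros((2, 2)))
    assert len(toroid.neighbor_indices(0)) == 8


def test_stratified_split_is_balanced_and_seeded():
    labels = ["a"] * 10 + ["b"] * 7 + ["c"] * 3
    train, test = stratified_split(labels, 0.5, random_state=1)
    assert len(train) + len(test) == 20
    assert set(train).isdisjoint(test)
    labels_arr = np.array(labels)
    assert sorted(labels_arr[train].tolist()).count("a") == 5
    assert sorted(labels_arr[train].tolist()).count("b") == 4  # ceil(3.5)
    again, _ = stratified_split(labels, 0.5, random_state=1)
    np.testing.assert_array_equal(train, again)


def test_cross_distance_tanimoto_on_binary_vectors():
    a = np.array([[1, 1, 0, 0]], dtype=float)
    b = np.array([[1, 0, 1, 0]], dtype=float)
    d = _cross_distances(a, b, "tanimoto_dissimilarity")
    assert d[0, 0] == pytest.approx(1 - 1 / 3)
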
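import numpy as np
import pytest

from maskov import GenotypeMatrix, HET, HOM, MISSING


@pytest.fixture
def rng():
    return np.random.default_rng(20130214)


def random_matrix(rng, n_markers=12, n_individuals=6, n_groups=2, p_missing=0.2):
    """Arbitrary valid genotype matrix for round-trip style tests."""
    calls = rng.choice(
        np.array([MISSING, HET, HOM], dtype=np.int8),
        size=(n_markers, n_individuals),
        p=[p_missing, (1 - p_missing) / 2, (1 - p_missing) / 2],
    )
    per_group = np.array_split(np.arange(n_markers), n_groups)
    lg = np.empty(n_markers, dtype=object)
    order = np.empty(n_markers, dtype=np.int64)
    for g, rows in enumerate(per_group):
        lg[rows] = f"LG{g + 1}"
        order[rows] = rng.permutation(len(rows))
    return GenotypeMatrix(
        calls=calls,
        marker_ids=[f"M{i}" for i in range(n_markers)],
        linkage_group=lg,
        order_index=order,
        individual_ids=[f"ind{j}" for j in range(n_individuals)],
    )


@pytest.fixture
def small_matrix():
    """3 markers x 2 individuals, one group, hand-written calls."""
    return GenotypeMatrix(
        calls=np.array([[HET, HOM], [MISSING, HET], [HOM, HOM]], dtype=np.int8),
        marker_ids=["M1", "M2", "M3"],
        linkage_group=np.array(["LG1"] * 3, dtype=object),
        order_index=np.array([0, 1, 2]),
        individual_ids=["ind1", "ind2"],
    )


def min_hamming_piecewise(v, k):
    """Brute-force minimum Hamming distance from v (over {+-1}) to any
    piecewise-constant {+-1} vector with exactly k sign changes."""
    import itertools

    v = np.asarray(v, dtype=np.int64)
    n = len(v)
    prefix = np.concatenate([[0], np.cumsum(v)])
    best = n + 1
    for bounds in itertools.combinations(range(1, n), k):
        bb = list(bounds) + [n]
        for s0 in (1, -1):
            cost = 0
            s, prev = s0, 0
            for b in bb:
                seg_sum = prefix[b] - prefix[prev]
                cost += ((b - prev) - s * seg_sum) // 2
                s, prev = -s, b
            if cost < best:
                best = cost
    return best
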
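import numpy as np
import pytest

from netsig.roi import RoiSet
from netsig.graph import Partition


@pytest.fixture
def rs3():
    return RoiSet.from_labels(["A", "B", "C"])


@pytest.fixture
def rs6():
    return RoiSet.default(6)


@pytest.fixture
def two_k3():
    """Two disconnected triangles on 6 nodes."""
    adj = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        adj[a, b] = adj[b, a] = 1.0
    return adj


@pytest.fixture
def two_k3_partition(rs6):
    return Partition(
        assignment={rs6[i]: (1 if i < 3 else 2) for i in range(6)},
        q=0.5,
        roi_set=rs6,
    )


def exhaustive_best_q(adj):
    """Brute-force maximum modularity over all set partitions (oracle)."""
    from netsig.graph import modularity_q

    n = adj.shape[0]

    def partitions(items):
        if len(items) == 1:
            yield [items]
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best_labels = -2.0, None
    for p in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for cid, members in enumerate(p):
            labels[members] = cid
        q = modularity_q(adj, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels
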
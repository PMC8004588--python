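import numpy as np
import pytest

import volqsrr as v


@pytest.fixture(scope="session")
def table():
    """The packaged two-year volatiles table."""
    return v.load_table()


@pytest.fixture(scope="session")
def mandatory_features(table):
    """The seven-descriptor feature table for identified compounds."""
    return v.descriptor_table(table, names=v.MANDATORY_DESCRIPTORS)


@pytest.fixture
def ethanol():
    return v.from_smiles("CCO")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bfs_distances(graph):
    """Independent pure-python BFS all-pairs bond-count distances."""
    n = graph.n_atoms
    adj = [[] for _ in range(n)]
    for i, j, _ in graph.bonds:
        adj[i].append(j)
        adj[j].append(i)
    out = [[None] * n for _ in range(n)]
    for s in range(n):
        out[s][s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if out[s][w] is None:
                        out[s][w] = d
                        nxt.append(w)
            frontier = nxt
    return out


def autocorrelation_oracle(graph, k, weights, kind):
    """Brute-force double-loop autocorrelation over ordered pairs."""
    import math

    d = bfs_distances(graph)
    n = graph.n_atoms
    w = list(weights)
    wbar = sum(w) / n
    pairs = [(i, j) for i in range(n) for j in range(n)
             if i != j and d[i][j] == k]
    nk = len(pairs)
    if kind == "ATSC":
        return sum((w[i] - wbar) * (w[j] - wbar) for i, j in pairs)
    if nk == 0:
        return 0.0
    if kind == "AATSC":
        return sum((w[i] - wbar) * (w[j] - wbar) for i, j in pairs) / nk
    ssd = sum((x - wbar) ** 2 for x in w)
    if kind == "MATS":
        denom = ssd / n
        if denom == 0:
            return 0.0
        num = sum((w[i] - wbar) * (w[j] - wbar) for i, j in pairs) / nk
        return num / denom
    if kind == "GATS":
        denom = ssd / (n - 1)
        if denom == 0:
            return 0.0
        num = sum((w[i] - w[j]) ** 2 for i, j in pairs) / (2 * nk)
        return num / denom
    raise ValueError(kind)
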
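import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Independent oracles used across test modules
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Dynamic-programming edit distance (oracle).

    Row recurrence with the left-neighbour dependency resolved as a
    prefix minimum: cur[j] = min_k<=j (candidate[k] + (j - k)).
    """
    bb = np.frombuffer(b.encode(), dtype="S1")
    idx = np.arange(len(b) + 1)
    prev = idx.copy()
    for i, ca in enumerate(a, 1):
        sub = prev[:-1] + (bb != ca.encode())
        cand = np.concatenate(([i], np.minimum(prev[1:] + 1, sub)))
        prev = np.minimum.accumulate(cand - idx) + idx
    return int(prev[-1])


def single_linkage_components(seqs, d):
    """Brute-force partition at edit-distance threshold d (oracle)."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if levenshtein(seqs[i], seqs[j]) <= d:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(seqs[i])
    return {frozenset(g) for g in groups.values()}


def gotoh_global(a: str, b: str, match=5.0, mismatch=-4.0, open_=-10.0, ext=-1.0):
    """Exhaustive affine-gap global alignment score (oracle).

    A gap of length k costs open_ + (k - 1) * ext.
    """
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    return max(M[n, m], X[n, m], Y[n, m])


def random_amplicon_set(rng, n_roots, n_total, length_range=(15, 25)):
    """Random sequences clustered around a few roots, for clustering tests."""
    bases = np.array(list("ACGT"))
    roots = []
    for _ in range(n_roots):
        L = int(rng.integers(*length_range))
        roots.append("".join(rng.choice(bases, size=L)))
    seqs = set(roots)
    while len(seqs) < n_total:
        s = list(roots[int(rng.integers(n_roots))])
        for _ in range(int(rng.integers(0, 4))):
            op = rng.integers(3)
            pos = int(rng.integers(len(s)))
            if op == 0:
                s[pos] = str(rng.choice(bases))
            elif op == 1 and len(s) > 5:
                del s[pos]
            else:
                s.insert(pos, str(rng.choice(bases)))
        seqs.add("".join(s))
    return sorted(seqs)
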
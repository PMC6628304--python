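import numpy as np
import pytest

from diallelkit import DiallelDesign, TruthParams, simulate_diallel


@pytest.fixture
def design5():
    return DiallelDesign([f"P{i}" for i in range(1, 6)], blocks=3)


@pytest.fixture
def design10():
    return DiallelDesign([f"P{i}" for i in range(1, 11)], blocks=3)


@pytest.fixture
def plots5(design5):
    """A simulated 5-parent, 3-block plot table with moderate noise."""
    params = TruthParams(mu=10.0, sigma2_g=4.0, sigma2_s=1.0,
                         sigma2_block=0.5, sigma2_e=1.0)
    return simulate_diallel(design5, params, trait="trait", seed=11)


def brute_force_upgma_heights(d: np.ndarray, labels):
    """Independent UPGMA reference: cluster distances recomputed from the
    original matrix as the mean over all inter-cluster leaf pairs.

    Returns the cophenetic distance matrix (labels x labels) implied by the
    merges, using the same lexicographic tie-break contract as the library.
    """
    n = len(labels)
    clusters = [frozenset([labels[i]]) for i in range(n)]
    pos = {lab: i for i, lab in enumerate(labels)}
    coph = np.zeros((n, n))

    def cdist(a, b):
        vals = [d[pos[u], pos[v]] for u in a for v in b]
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                key = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                cand = (cdist(clusters[i], clusters[j]), key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, i, j = best
        for u in clusters[i]:
            for v in clusters[j]:
                coph[pos[u], pos[v]] = coph[pos[v], pos[u]] = dist
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return coph
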
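"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — plain Python loops and math — and
shares no code path with the package.
"""

import math
from itertools import combinations


def naive_kde(eigenvalues, grid, bandwidth):
    """Direct per-kernel Gaussian sum, un-normalized then trapezoid-normalized."""
    n = len(eigenvalues)
    raw = []
    for x in grid:
        s = 0.0
        for lam in eigenvalues:
            z = (x - lam) / bandwidth
            s += math.exp(-0.5 * z * z) / (bandwidth * math.sqrt(2 * math.pi))
        raw.append(s / n)
    area = 0.0
    for i in range(len(grid) - 1):
        area += 0.5 * (raw[i] + raw[i + 1]) * (grid[i + 1] - grid[i])
    return [v / area for v in raw]


def naive_kl(p, q):
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(pi / qi)
    return total


def naive_js(p, q):
    m = [(pi + qi) / 2 for pi, qi in zip(p, q)]
    return 0.5 * naive_kl(p, m) + 0.5 * naive_kl(q, m)


def pair_counting_ari(labels_true, labels_pred):
    """ARI from explicit agreement counts over all item pairs."""
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(len(labels_true)), 2):
        same_t = labels_true[i] == labels_true[j]
        same_p = labels_pred[i] == labels_pred[j]
        if same_t and same_p:
            n11 += 1
        elif not same_t and not same_p:
            n00 += 1
        elif same_t:
            n10 += 1
        else:
            n01 += 1
    num = 2 * (n00 * n11 - n01 * n10)
    den = (n00 + n01) * (n01 + n11) + (n00 + n10) * (n10 + n11)
    return num / den if den else 1.0


def set_partitions(items):
    """All set partitions of a sequence (each as a tuple of blocks)."""
    items = list(items)
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + ((first,) + partial[i],) + partial[i + 1 :]
        yield ((first,),) + partial


def partition_to_labels(partition, n):
    labels = [0] * n
    for c, block in enumerate(partition):
        for item in block:
            labels[item] = c
    return labels
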
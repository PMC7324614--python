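"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (exhaustive counting, O(n^2) scans) kept
free of any code path they are checking.
"""

from collections import Counter

import numpy as np


def brute_consensus(seqs, min_agreement=0.8, small_group_max=4):
    """Exhaustive consensus of a UMI group: (sequence, min fraction, support) or None."""
    length_counts = Counter(len(s) for s in seqs)
    ranked = length_counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    sub = [s for s in seqs if len(s) == ranked[0][0]]
    n = len(sub)
    if n <= small_group_max:
        return (sub[0], 1.0, n) if len(set(sub)) == 1 else None
    cons = []
    min_frac = 1.0
    for i in range(len(sub[0])):
        counts = Counter(s[i] for s in sub)
        base, top = counts.most_common(1)[0]
        frac = top / n
        min_frac = min(min_frac, frac)
        cons.append(base)
    if min_frac < min_agreement:
        return None
    return "".join(cons), min_frac, n


def brute_hamming_edges(seqs):
    """All pairs at Hamming distance exactly 1 (equal lengths only), O(n^2)."""
    seqs = sorted(set(seqs))
    edges = set()
    by_len = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    for group in by_len.values():
        arr = np.frombuffer("".join(group).encode(), dtype=np.uint8).reshape(
            len(group), -1
        )
        dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        for i, k in zip(*np.nonzero(dist == 1)):
            if i < k:
                edges.add((group[i], group[k]))
    return edges


def random_group(rng, size, length, error_rate):
    """Reads of one UMI group: a true sequence plus iid substitution errors."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    true = bases[rng.integers(0, 4, size=length)]
    reads = []
    for _ in range(size):
        r = true.copy()
        hits = np.nonzero(rng.random(length) < error_rate)[0]
        if hits.size:
            r[hits] = bases[(np.searchsorted(bases, r[hits]) + rng.integers(1, 4, hits.size)) % 4]
        reads.append(r.tobytes().decode())
    return reads
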
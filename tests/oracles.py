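"""Independent brute-force oracles used to validate the fast implementations.

The clustering oracle enumerates the maximal-scoring-segment decomposition
at every density regime using exact rational arithmetic and the textbook
Ruzzo-Tompa algorithm, entirely independently of the recursive
implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def rt_maximal_segments(pos, cnt, d: Fraction) -> set[tuple[int, int]]:
    """All maximal scoring subsequences at density ``d`` (Ruzzo-Tompa).

    The score sequence alternates +count at each site and ``-d * gap``
    between consecutive sites. Returns site-index ranges (i, j) inclusive.
    """
    scores: list[Fraction] = []
    for k in range(len(pos)):
        if k:
            scores.append(-d * (pos[k] - pos[k - 1]))
        scores.append(Fraction(int(cnt[k])))

    # stack entries: [start_elem, end_elem, L, R]
    stack: list[list] = []
    cum = Fraction(0)
    for idx, s in enumerate(scores):
        if s > 0:
            new = [idx, idx, cum, cum + s]
            cum += s
            while True:
                j = None
                for jj in range(len(stack) - 1, -1, -1):
                    if stack[jj][2] < new[2]:
                        j = jj
                        break
                if j is None or stack[j][3] >= new[3]:
                    stack.append(new)
                    break
                merged = [stack[j][0], new[1], stack[j][2], new[3]]
                del stack[j:]
                new = merged
        else:
            cum += s
    # element index -> site index: site k is element 2k
    return {(a // 2, b // 2) for a, b, _, _ in stack}


def brute_force_hierarchy(pos, cnt) -> dict[tuple[int, int], tuple[float, float]]:
    """Every segment that is maximal scoring for some density d > 0, with the
    infimum and supremum of its density interval (as floats; inf for
    unbounded, 0 for segments maximal down to d -> 0+).

    Candidate critical densities are every prefix/suffix break density of
    every contiguous site range plus every segment's own mean density; the
    decomposition is evaluated with exact rationals at midpoints between
    consecutive candidates and beyond both extremes.
    """
    n = len(pos)
    if n == 0:
        return {}
    pos = [int(p) for p in pos]
    cnt = [int(c) for c in cnt]
    pre = [0]
    for c in cnt:
        pre.append(pre[-1] + c)

    candidates: set[Fraction] = set()
    for a in range(n):
        for b in range(a + 1, n):
            for k in range(a + 1, b + 1):
                candidates.add(Fraction(pre[k] - pre[a], pos[k] - pos[a]))
                candidates.add(Fraction(pre[b + 1] - pre[k], pos[b] - pos[k - 1]))
            candidates.add(Fraction(pre[b + 1] - pre[a], pos[b] - pos[a]))
    cand = sorted(candidates)

    if not cand:  # single site: maximal for every d
        return {(0, 0): (0.0, float("inf"))}

    test_ds = [cand[0] / 2]
    for lo, hi in zip(cand, cand[1:]):
        test_ds.append((lo + hi) / 2)
    test_ds.append(cand[-1] + 1)

    present: dict[tuple[int, int], list[int]] = {}
    for ti, d in enumerate(test_ds):
        for seg in rt_maximal_segments(pos, cnt, d):
            present.setdefault(seg, []).append(ti)

    out: dict[tuple[int, int], tuple[float, float]] = {}
    for seg, tis in present.items():
        assert tis == list(range(tis[0], tis[-1] + 1)), "non-contiguous density range"
        first, last = tis[0], tis[-1]
        min_d = 0.0 if first == 0 else float(cand[first - 1])
        max_d = float("inf") if last == len(test_ds) - 1 else float(cand[last])
        out[seg] = (min_d, max_d)
    return out


def random_sites(rng: np.random.Generator, max_sites: int = 12):
    """Random CTSS input matching the oracle-equivalence study conditions:
    up to 12 sites, positions uniform on [0, 500], counts uniform 1..20."""
    n = int(rng.integers(1, max_sites + 1))
    pos = np.sort(rng.choice(501, size=n, replace=False))
    cnt = rng.integers(1, 21, size=n)
    return pos, cnt
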
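"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def threshold_sweep_persistence(f):
    """0-D sublevel persistence by explicit threshold sweep.

    Points are inserted one at a time in ascending (value, index) order; the
    connected components of the current sublevel set are recomputed from the
    boolean mask at every step (no union-find).  When the inserted point
    fuses two or more runs, every run except the one holding the eldest
    (smallest (value, index)) minimum dies there.

    Returns (pairs, essential) with pairs a set of tuples
    (birth, death, birth_index, death_index) and essential a tuple
    (value, index) of the global minimum.
    """
    f = np.asarray(f, dtype=float)
    n = f.size
    order = sorted(range(n), key=lambda i: (f[i], i))
    mask = np.zeros(n, dtype=bool)

    def runs_of(mask):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return []
        cuts = np.flatnonzero(np.diff(idx) > 1) + 1
        return [(int(g[0]), int(g[-1])) for g in np.split(idx, cuts)]

    def birth_of(run):
        lo, hi = run
        seg = f[lo : hi + 1]
        j = int(np.lexsort((np.arange(lo, hi + 1), seg))[0])
        return (float(seg[j]), lo + j)

    pairs = set()
    prev_runs: list[tuple[int, int]] = []
    for i in order:
        mask[i] = True
        new_runs = runs_of(mask)
        container = next(r for r in new_runs if r[0] <= i <= r[1])
        swallowed = [r for r in prev_runs if container[0] <= r[0] and r[1] <= container[1]]
        if len(swallowed) >= 2:
            births = sorted(birth_of(r) for r in swallowed)
            for b_val, b_idx in births[1:]:
                pairs.add((b_val, float(f[i]), b_idx, int(i)))
        prev_runs = new_runs
    essential = min((float(f[i]), int(i)) for i in range(n))
    return pairs, essential
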
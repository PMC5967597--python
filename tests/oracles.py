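"""Independent brute-force oracles for the shape-constrained fits.

The optimal isotonic fit is piecewise constant on blocks with block values
equal to block means and monotone across blocks, so enumerating all
2^(n-1) contiguous block partitions and keeping those with monotone means
yields the exact least-squares optimum.  The unimodal oracle scans every
mode split and combines the increasing/decreasing partition oracles.
These never call the package's fitting code.
"""

from __future__ import annotations

import itertools

import numpy as np


def monotone_oracle_sse(y, increasing: bool) -> float:
    """Exact min SSE over monotone step functions, by partition enumeration."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return 0.0
    best = np.inf
    for cuts in itertools.product([False, True], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        diffs = np.diff(means)
        ok = np.all(diffs >= -1e-12) if increasing else np.all(diffs <= 1e-12)
        if not ok:
            continue
        sse = sum(float(np.sum((y[a:b] - m) ** 2))
                  for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means))
        if sse < best:
            best = sse
    return best


def unimodal_oracle_sse(y) -> float:
    """Exact min SSE over up-then-down step functions (mode scan + oracles)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    best = np.inf
    for m in range(n + 1):
        s = monotone_oracle_sse(y[:m], increasing=True) + \
            monotone_oracle_sse(y[m:], increasing=False)
        if s < best:
            best = s
    return best
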
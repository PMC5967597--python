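"""Shape-constrained least-squares step fits: isotonic and unimodal.

These are the nonparametric regression classes used for the radial uptake
profile: nonincreasing step functions (pool-adjacent-violators, PAVA) and
unimodal ("bitonic", up-then-down) step functions obtained by scanning the
mode position and concatenating an increasing-isotonic prefix fit with a
decreasing-isotonic suffix fit.  Since the nonincreasing class is nested in
the unimodal class (mode at position 0), SSE(unimodal) <= SSE(decreasing)
on every input.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import isotonic_regression as _scipy_pava


def _pava(y, sample_weight=None, increasing=True):
    res = _scipy_pava(np.ascontiguousarray(y, dtype=float),
                      weights=sample_weight, increasing=increasing)
    return np.asarray(res.x)


def _check_xy(u, y):
    u = np.asarray(u, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if u.shape != y.shape:
        raise ValueError(f"u and y lengths differ: {u.size} vs {y.size}")
    if u.size == 0:
        raise ValueError("empty input")
    return u, y


def isotonic_decreasing_fit(u, y, sample_weight=None) -> np.ndarray:
    """Least-squares nonincreasing step fit of y against the ordering of u.

    ``u`` must already be sorted nondecreasing (stable sort of radii is the
    caller's responsibility); returns fitted values aligned with the input.
    """
    u, y = _check_xy(u, y)
    return _pava(y, sample_weight=sample_weight, increasing=False)


def isotonic_increasing_fit(u, y, sample_weight=None) -> np.ndarray:
    """Least-squares nondecreasing step fit (same conventions as above)."""
    u, y = _check_xy(u, y)
    return _pava(y, sample_weight=sample_weight, increasing=True)


def _prefix_suffix_sse(y, w, mode, fit_out=None):
    """SSE of increasing fit on y[:mode] plus decreasing fit on y[mode:]."""
    sse = 0.0
    if fit_out is not None:
        fit = fit_out
    else:
        fit = np.empty_like(y)
    if mode > 0:
        inc = _pava(y[:mode], sample_weight=None if w is None else w[:mode], increasing=True)
        fit[:mode] = inc
    if mode < y.size:
        dec = _pava(y[mode:], sample_weight=None if w is None else w[mode:], increasing=False)
        fit[mode:] = dec
    r = y - fit
    sse = float(np.sum(r * r) if w is None else np.sum(w * r * r))
    return sse, fit


def unimodal_fit(u, y, sample_weight=None, max_modes: int | None = None):
    """Least-squares unimodal (up-then-down) step fit.

    Scans candidate mode positions m in {0, ..., n}: positions < m are fit
    by an increasing isotonic regression, positions >= m by a decreasing
    one; the pair minimizing the (weighted) SSE wins.  m = 0 reduces to the
    pure nonincreasing fit, so the returned SSE never exceeds the
    decreasing-isotonic SSE.

    When ``max_modes`` is given and n is large, candidates are restricted to
    about that many equally spaced order-statistic positions (0 and n always
    included).

    Returns ``(fit, mode_index, sse)`` where ``mode_index`` is the position
    of the (first) maximal fitted value.
    """
    u, y = _check_xy(u, y)
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float).ravel()
    n = y.size
    if max_modes is not None and n + 1 > max_modes:
        cand = np.unique(np.round(np.linspace(0, n, max_modes)).astype(int))
    else:
        cand = np.arange(n + 1)

    best_sse = np.inf
    best_fit = None
    for m in cand:
        sse, fit = _prefix_suffix_sse(y, w, int(m))
        if sse < best_sse:
            best_sse = sse
            best_fit = fit.copy()
    mode_index = int(np.argmax(best_fit))
    return best_fit, mode_index, best_sse


def sse(y, fit, sample_weight=None) -> float:
    r = np.asarray(y, dtype=float) - np.asarray(fit, dtype=float)
    if sample_weight is None:
        return float(np.sum(r * r))
    return float(np.sum(np.asarray(sample_weight, dtype=float) * r * r))
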
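"""Independent brute-force oracles used to cross-check the implementation."""

import itertools

import numpy as np

SQRT2 = float(np.sqrt(2.0))


def total_skeleton_length(raster: np.ndarray, scale: float = 1.0) -> float:
    """Total length by scanning every unique 8-adjacent pixel pair."""
    pts = list(map(tuple, np.argwhere(raster)))
    pset = set(pts)
    total = 0.0
    for (r, c) in pts:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # each pair once
            if (r + dr, c + dc) in pset:
                total += SQRT2 if dr and dc else 1.0
    return total * scale


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Assumes nonzero differences with untied absolute values.
    """
    d = np.asarray(diffs, float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    w_mean = n * (n + 1) / 4.0
    obs_dev = abs(w_plus - w_mean)
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - w_mean) >= obs_dev - 1e-12:
            count += 1
    return count / 2.0 ** n


def chi2_2x2_p(table) -> float:
    """Pearson chi-square p from the Σ(O−E)²/E definition, df = 1."""
    from scipy.stats import chi2

    t = np.asarray(table, float)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (t[i, j] - e) ** 2 / e
    return float(chi2.sf(stat, 1))
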
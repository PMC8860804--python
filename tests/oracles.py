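"""Independent brute-force oracles used to cross-check the package.

Every function here is deliberately written from the mathematical
definition, in a different style (plain loops, eigendecompositions,
explicit sums of squares) from the implementation it checks, and never
calls into :mod:`dirconn`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def dpli_loop(phase_x, phase_y) -> float:
    """Heaviside-sum dPLI by explicit loop; H(0) = 1/2."""
    total = 0.0
    n = len(phase_x)
    for px, py in zip(phase_x, phase_y):
        d = math.atan2(math.sin(px - py), math.cos(px - py))
        if d > 0:
            total += 1.0
        elif d == 0:
            total += 0.5
    return total / n


def nmi_direct(phase_lo, amp_hi) -> float:
    """Direct evaluation of the normalized modulation index formula."""
    n = len(phase_lo)
    acc = 0.0 + 0.0j
    sq = 0.0
    for p, a in zip(phase_lo, amp_hi):
        acc += a * complex(math.cos(p), math.sin(p))
        sq += a * a
    return abs(acc) / (math.sqrt(n) * math.sqrt(sq))


def leading_component_gram(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal time course via eigendecomposition of the row
    Gram matrix, sign-corrected by a manual majority count."""
    X = np.asarray(X, dtype=float)
    gram = X @ X.T
    evals, evecs = np.linalg.eigh(gram)
    w = evecs[:, -1]
    tc = w @ X  # scaled right singular vector: s * v
    n_pos = sum(1 for wi in w if wi > 0)
    n_neg = sum(1 for wi in w if wi < 0)
    if n_pos < n_neg:
        w, tc = -w, -tc
    return tc, w


def union_find_components(nodes, edges) -> list[set]:
    """Weakly connected components via union-find on the undirected
    projection of a directed edge set."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def anova_sums_of_squares(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook one-way ANOVA from explicit between/within sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2)) for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def fft_hilbert(x: np.ndarray) -> np.ndarray:
    """Frequency-domain analytic signal: double positive frequencies,
    zero negative ones."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spec * h)
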
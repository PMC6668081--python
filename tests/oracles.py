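"""Independent brute-force oracles used to validate the package.

Everything here is written deliberately as plain per-observation Python
loops over dictionaries, independent of the vectorized implementations in
``redalpha``, so agreement between the two is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# geometry


def torsion_oracle(p0, p1, p2, p3) -> float:
    """Torsion angle by the projection construction, mapped to [0, 2*pi)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = -math.atan2(y, x)
    return ang + 2.0 * math.pi if ang < 0 else ang


def nearest_seed_oracle(point, seeds) -> int:
    """1-based index of the closest seed by linear scan (ties: lowest)."""
    best, best_d = None, float("inf")
    for i, s in enumerate(seeds):
        d = (point[0] - s[0]) ** 2 + (point[1] - s[1]) ** 2
        if d < best_d:
            best, best_d = i, d
    return best + 1


def min_atom_distance_oracle(atoms_a, atoms_b) -> float:
    """Minimum pairwise distance by explicit double loop."""
    best = float("inf")
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist(list(a), list(b))
            best = min(best, d)
    return best


# ---------------------------------------------------------------------------
# mutual information (direct per-observation summation)


def _freqs(n_joint, n_cond, n_state, n, n_states, lam, loo):
    sub = 1.0 if loo else 0.0
    bg = n_state / n
    fcond = (n_joint - sub + lam * bg) / (n_cond - sub + lam)
    fmarg = (n_state - sub + lam / n_states) / (n - sub + lam)
    return fcond, fmarg


def mi_backbone_oracle(trimers, cells, k, lam=1.0, loo=True, rule_map=None):
    """(1/n) sum ln f(cell|trimer)/f(cell); trimers are 3-letter strings."""
    red = [
        t if rule_map is None else "".join(rule_map[a] for a in t) for t in trimers
    ]
    n = len(cells)
    n_cell = Counter(cells)
    n_tri = Counter(red)
    n_joint = Counter(zip(red, cells))
    total = 0.0
    for t, c in zip(red, cells):
        fcond, fmarg = _freqs(
            n_joint[(t, c)], n_tri[t], n_cell[c], n, k, lam, loo
        )
        total += math.log(fcond / fmarg)
    return total / n


def mi_backbone_norm_oracle(trimers, cells, k, lam=1.0, loo=True, rule_map=None):
    """Mean per-occurrence log-ratio per full trimer, averaged over 8000."""
    red = [
        t if rule_map is None else "".join(rule_map[a] for a in t) for t in trimers
    ]
    n = len(cells)
    n_cell = Counter(cells)
    n_tri = Counter(red)
    n_joint = Counter(zip(red, cells))
    n_full = Counter(trimers)
    total = 0.0
    for t_full, t, c in zip(trimers, red, cells):
        fcond, fmarg = _freqs(
            n_joint[(t, c)], n_tri[t], n_cell[c], n, k, lam, loo
        )
        total += math.log(fcond / fmarg) / n_full[t_full]
    return total / 8000.0


def mi_contact_oracle(pairs, bins, m, n_d, lam=1.0, loo=True, rule_map=None):
    """(1/n_d) * double-counted sum of ln f(bin|pair)/f(bin)."""
    red = []
    for a, b in pairs:
        if rule_map is not None:
            a, b = rule_map[a], rule_map[b]
        red.append(tuple(sorted((a, b))))
    nc = len(bins)
    n_bin = Counter(bins)
    n_pair = Counter(red)
    n_joint = Counter(zip(red, bins))
    total = 0.0
    for p, b in zip(red, bins):
        fcond, fmarg = _freqs(
            n_joint[(p, b)], n_pair[p], n_bin[b], nc, m, lam, loo
        )
        total += math.log(fcond / fmarg)
    return 2.0 * total / n_d


def closed_form_mi(p_joint: np.ndarray) -> float:
    """MI in nats of a discrete joint distribution by direct summation."""
    p = np.asarray(p_joint, dtype=float)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / (px @ py)[mask])).sum())
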
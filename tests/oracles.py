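"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit neighbour enumeration, BFS,
exhaustive sign-flip enumeration, label permutation.  None of it shares code
with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order == 1:
            offsets.append(d)
        elif connectivity == 18 and order <= 2:
            offsets.append(d)
        elif connectivity == 26:
            offsets.append(d)
    return offsets


def bfs_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int, int]]]:
    """Connected components of a 3D boolean array by explicit BFS."""
    offsets = neighbour_offsets(connectivity)
    remaining = {tuple(c) for c in np.argwhere(mask)}
    shape = mask.shape
    components = []
    while remaining:
        start = min(remaining)  # deterministic
        comp = {start}
        remaining.remove(start)
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and w in remaining:
                    remaining.remove(w)
                    comp.add(w)
                    queue.append(w)
        components.append(comp)
    return components


def match_lesions_bruteforce(labels: np.ndarray, pred: np.ndarray, tau: float, connectivity: int):
    """(per-label overlap fraction, detected flags, fp cluster count) via sets."""
    pred_set = {tuple(c) for c in np.argwhere(pred)}
    gt_set = {tuple(c) for c in np.argwhere(labels > 0)}
    fractions = {}
    detected = {}
    for label in sorted(int(v) for v in np.unique(labels) if v):
        lesion = {tuple(c) for c in np.argwhere(labels == label)}
        frac = len(lesion & pred_set) / len(lesion)
        fractions[label] = frac
        detected[label] = frac >= tau
    fp = sum(1 for comp in bfs_components(pred, connectivity) if not comp & gt_set)
    return fractions, detected, fp


def voxel_metrics_bruteforce(gt: np.ndarray, pred: np.ndarray):
    """(dsc, sensitivity, ppv, specificity) as percentages via set arithmetic."""
    a = {tuple(c) for c in np.argwhere(gt)}
    b = {tuple(c) for c in np.argwhere(pred)}
    inter = len(a & b)
    total = gt.size
    tn = total - len(a | b)
    dsc = 100.0 * 2 * inter / (len(a) + len(b))
    sens = 100.0 * inter / len(a)
    ppv = 100.0 * inter / len(b) if b else 0.0
    spec = 100.0 * tn / (total - len(a))
    return dsc, sens, ppv, spec


def wilcoxon_exact_two_sided(differences) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Uses mid-ranks of |d| and the convention p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = absd.argsort(kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        midrank = (pos + pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        pos += j - i + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    le = ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs + 1e-12:
            le += 1
        if w >= w_obs - 1e-12:
            ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


def logrank_permutation_p(times_a, events_a, times_b, events_b, n_perm=10_000, seed=0):
    """Permutation p-value for a group-difference score on censored data.

    Reference statistic: observed minus expected events in group A under the
    hypergeometric risk-set model (the log-rank numerator), re-computed over
    random relabellings.
    """
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b]).astype(bool)
    na = len(times_a)
    rng = np.random.default_rng(seed)

    def score(is_a: np.ndarray) -> float:
        obs_minus_exp = 0.0
        for t in np.unique(times[events]):
            at_risk = times >= t
            d = int((events & (times == t)).sum())
            n_risk = int(at_risk.sum())
            d_a = int((events & (times == t) & is_a).sum())
            n_a = int((at_risk & is_a).sum())
            obs_minus_exp += d_a - d * n_a / n_risk
        return abs(obs_minus_exp)

    base = np.zeros(len(times), dtype=bool)
    base[:na] = True
    observed = score(base)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(times))
        hits += score(base[perm]) >= observed - 1e-12
    return (hits + 1) / (n_perm + 1)


def km_product_limit(times, events):
    """Hand product-limit estimator: [(event time, S after)] pairs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    curve = []
    for t in sorted(set(times[events])):
        n_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_risk
        curve.append((t, s))
    return curve
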
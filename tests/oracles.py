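"""Independent brute-force oracles used by unit and acceptance tests.

Every function here recomputes a pipeline quantity by direct enumeration or
naive loops, deliberately sharing no code with the implementation under
test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gfp_direct(map_values: np.ndarray) -> float:
    """Population standard deviation across channels via an explicit loop."""
    c = len(map_values)
    mean = sum(map_values) / c
    return math.sqrt(sum((v - mean) ** 2 for v in map_values) / c)


def assign_exhaustive(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Nearest template by maximal squared correlation, pairwise loops."""
    labels = []
    for x in maps:
        best_k, best_val = None, -1.0
        for k, a in enumerate(templates, start=1):
            c = float(np.dot(x, a) / (np.linalg.norm(x) * np.linalg.norm(a)))
            if c**2 > best_val:
                best_k, best_val = k, c**2
        labels.append(best_k)
    return np.asarray(labels)


def gev_direct(
    maps: np.ndarray,
    gfp: np.ndarray,
    templates: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Per-sample GEV summation, one term at a time."""
    denom = sum(g**2 for g in gfp)
    per_class = np.zeros(templates.shape[0])
    for x, g, l in zip(maps, gfp, labels):
        a = templates[l - 1]
        corr = float(np.dot(x, a) / (np.linalg.norm(x) * np.linalg.norm(a)))
        per_class[l - 1] += corr**2 * g**2 / denom
    return float(per_class.sum()), per_class


def best_gev_over_labelings(maps: np.ndarray, gfp: np.ndarray, K: int) -> float:
    """Maximum GEV over every labelling, centres as sign-aligned means.

    For each labelling the class centre is the mean of the member maps after
    flipping each to agree in sign with the first member, re-centred and
    normalised — the centre definition of polarity-invariant clustering.
    GEV is then summed per sample against those centres.
    """
    m = maps.shape[0]
    denom = float(np.sum(gfp**2))
    best = 0.0
    for labeling in itertools.product(range(1, K + 1), repeat=m):
        labeling = np.asarray(labeling)
        centres = []
        valid = True
        for k in range(1, K + 1):
            members = maps[labeling == k]
            if members.shape[0] == 0:
                valid = False
                break
            signs = np.sign(members @ members[0])
            signs[signs == 0] = 1.0
            c = (members * signs[:, None]).mean(axis=0)
            c = c - c.mean()
            norm = np.linalg.norm(c)
            if norm == 0:
                valid = False
                break
            centres.append(c / norm)
        if not valid:
            continue
        total = 0.0
        for x, g, l in zip(maps, gfp, labeling):
            a = centres[l - 1]
            corr = float(np.dot(x, a) / np.linalg.norm(x))
            total += corr**2 * g**2 / denom
        best = max(best, total)
    return best


def window_objective(
    labels: np.ndarray, misfit: np.ndarray, b: int, lam: float
) -> float:
    """Smoothing objective, each agreeing unordered pair counted once."""
    n = len(labels)
    total = 0.0
    for i in range(n):
        total += misfit[i, labels[i] - 1]
        for j in range(i + 1, min(n, i + b + 1)):
            if labels[j] == labels[i]:
                total -= lam
    return total


def smooth_exhaustive(misfit: np.ndarray, K: int, b: int, lam: float) -> np.ndarray:
    """Globally optimal labelling of the smoothing objective by enumeration."""
    n = misfit.shape[0]
    best_labels, best_obj = None, np.inf
    for labeling in itertools.product(range(1, K + 1), repeat=n):
        obj = window_objective(np.asarray(labeling), misfit, b, lam)
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, np.asarray(labeling)
    return best_labels


def transition_counts(segment_labels: list[int], K: int) -> np.ndarray:
    """Hand-counted transition frequencies between consecutive segments."""
    counts = np.zeros((K, K))
    for a, b_ in zip(segment_labels, segment_labels[1:]):
        if a != b_:
            counts[a - 1, b_ - 1] += 1
    sums = counts.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return counts / sums


def ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating every group split."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(y)
    hi = max(u_obs, n1n2 - u_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(sorted(ranks.values())[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if u >= hi or u <= n1n2 - hi:
            count += 1
    return min(1.0, count / total)


def class_parameters_direct(labels, corr, gfp, fs, K):
    """Loop-based recomputation of the per-class parameter families."""
    n = len(labels)
    window_s = n / fs
    # run lengths
    segs = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            segs.append((labels[start], start, i))
            start = i
    out = {}
    denom = sum(g**2 for g in gfp)
    for k in range(1, K + 1):
        k_segs = [s for s in segs if s[0] == k]
        idx = [i for i in range(n) if labels[i] == k]
        occ = len(k_segs) / window_s
        dur = (
            float(np.mean([(e - s) / fs * 1000 for _, s, e in k_segs]))
            if k_segs
            else 0.0
        )
        cov = len(idx) / n
        gev_k = sum(corr[i] ** 2 * gfp[i] ** 2 / denom for i in idx)
        gfp_k = float(np.mean([gfp[i] for i in idx])) if idx else 0.0
        msc = float(np.mean([abs(corr[i]) for i in idx])) if idx else 0.0
        out[k] = dict(
            occurrence=occ, duration=dur, coverage=cov, gev=gev_k,
            gfp=gfp_k, mspatcorr=msc,
        )
    return out
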